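"""Geometric hydrogen-bond detection in protein coordinates.

Detects donor–H···acceptor bonds by the geometric rule used for docked
neck-linker analysis of kinesin motors: the donor–acceptor heavy-atom
distance must be below ``dmax`` (default 0.36 nm) and the angle at the
donor between the D→H and D→A directions must be below ``angle_max``
(default 30°).  Bonds between the neck linker (NL) and the motor domain
are classified into regions (N-latch, β7–β10, intra-NL, cover strand)
to produce latch reports of the kind used to compare NL variants.

Coordinates are stored in Å (the PDB convention); H-bond distances are
reported in nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "HBond",
    "LatchReport",
    "PDBParseError",
    "read_structure",
    "write_pdb",
    "place_amide_hydrogens",
    "enumerate_donors_acceptors",
    "detect_hbonds",
    "latch_report",
    "DEFAULT_DMAX_NM",
    "DEFAULT_ANGLE_MAX_DEG",
    "DEFAULT_REGION_MAP",
]

#: Stringent distance cutoff (nm) under which the reported bond arrays
#: were produced; the alternative 0.35 nm cutoff is available via the
#: ``dmax_nm`` argument of :func:`detect_hbonds`.
DEFAULT_DMAX_NM = 0.36
DEFAULT_ANGLE_MAX_DEG = 30.0

#: Distance (Å) below which a donor/acceptor heavy-atom pair is treated
#: as covalently bonded and excluded from H-bond detection.
COVALENT_CUTOFF_A = 2.0

BACKBONE_ATOMS = {"N", "CA", "C", "O"}

# Side-chain donor heavy atoms and the hydrogens attached to them.
SIDECHAIN_DONORS = {
    "SER": {"OG": ("HG",)},
    "THR": {"OG1": ("HG1",)},
    "ASN": {"ND2": ("HD21", "HD22")},
    "GLN": {"NE2": ("HE21", "HE22")},
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
}

# Side-chain acceptor heavy atoms.
SIDECHAIN_ACCEPTORS = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
}

#: Heavy atoms whose attached hydrogen can rotate about the preceding
#: covalent bond; for these the angle criterion may be evaluated at the
#: orientation that minimises it when no explicit H is present.
ROTATABLE_DONOR_ATOMS = {"OG", "OG1", "NZ"}

THREE_LETTER = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class PDBParseError(ValueError):
    """Raised when PDB input cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def key(self) -> tuple:
        return (self.chain, self.resnum, self.name)


@dataclass
class Structure:
    """A plain table of atoms with unique (chain, residue, atom) keys."""

    atoms: list[Atom]
    source_id: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinates for atom {a.key}")
            if a.key in self._index:
                raise ValueError(f"duplicate atom {a.key}")
            self._index[a.key] = a

    def __len__(self) -> int:
        return len(self.atoms)

    def get(self, chain: str, resnum: int, name: str) -> Atom | None:
        return self._index.get((chain, resnum, name))

    def residues(self) -> dict[tuple[str, int], list[Atom]]:
        out: dict[tuple[str, int], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault((a.chain, a.resnum), []).append(a)
        return out

    def with_atoms(self, extra: list[Atom]) -> "Structure":
        return Structure(self.atoms + list(extra), source_id=self.source_id)


@dataclass(frozen=True)
class HBond:
    donor: tuple[str, int, str, str]      # chain, resnum, resname, heavy atom
    hydrogen: str | None                  # H atom name, None if virtual
    acceptor: tuple[str, int, str, str]
    d_da_nm: float
    angle_adh_deg: float

    def __post_init__(self) -> None:
        if self.donor[:2] == self.acceptor[:2] and self.donor[3] == self.acceptor[3]:
            raise ValueError("donor and acceptor are the same atom")


@dataclass
class LatchReport:
    bonds: list[HBond]
    region_counts: dict[str, int]
    total: int
    conserved_latch_bond: bool


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_structure(pdb: str, source_id: str = "") -> Structure:
    """Parse PDB text (or a path to a ``.pdb`` file) into a :class:`Structure`.

    Only ATOM/HETATM coordinate records are used.  Alternate location A is
    kept (blank altlocs always); insertion codes are rejected because the
    kinesin residue numbering used downstream assumes plain integers.
    """
    if "\n" not in pdb and pdb.strip().endswith(".pdb"):
        with open(pdb) as fh:
            pdb = fh.read()
    try:
        st = gemmi.read_pdb_string(pdb)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line
        raise PDBParseError(f"malformed PDB input: {exc}") from exc
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                if res.seqid.icode not in (" ", ""):
                    raise PDBParseError(
                        f"insertion code {res.seqid.icode!r} at residue "
                        f"{chain.name}/{res.seqid.num} is not supported"
                    )
                for at in res:
                    if at.altloc not in ("", "A", "\x00"):
                        continue
                    atoms.append(
                        Atom(
                            chain=chain.name or "A",
                            resnum=res.seqid.num,
                            resname=res.name,
                            name=at.name,
                            element=at.element.name,
                            x=at.pos.x,
                            y=at.pos.y,
                            z=at.pos.z,
                        )
                    )
        break  # first model only
    if not atoms:
        raise PDBParseError("no ATOM records found")
    return Structure(atoms, source_id=source_id)


def write_pdb(structure: Structure, path: str | None = None) -> str:
    """Serialize a structure as fixed-width PDB ATOM records (Å)."""
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {i:5d} {name:<4s}{a.resname:>4s} {a.chain[:1]}"
            f"{a.resnum:4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
        )
    text = "\n".join(lines) + "\nEND\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Hydrogen placement
# ---------------------------------------------------------------------------

N_H_LENGTH_A = 1.01


def place_amide_hydrogens(s: Structure) -> Structure:
    """Add backbone amide hydrogens where they are missing.

    The H is placed 1.01 Å from N, in the C(i−1)–N–CA plane, opposite the
    bisector of that angle (trans-peptide geometry).  Prolines, chain
    N-termini (no preceding C within peptide-bond distance) and residues
    already carrying an H are left untouched.
    """
    by_res = s.residues()
    new: list[Atom] = []
    for (chain, resnum), atoms in by_res.items():
        names = {a.name for a in atoms}
        resname = atoms[0].resname
        if "H" in names or resname == "PRO":
            continue
        n = s.get(chain, resnum, "N")
        ca = s.get(chain, resnum, "CA")
        c_prev = s.get(chain, resnum - 1, "C")
        if n is None or ca is None:
            warnings.warn(
                f"residue {chain}/{resnum} lacks backbone N/CA; H not placed"
            )
            continue
        if c_prev is None or np.linalg.norm(c_prev.pos - n.pos) > 1.8:
            continue  # chain N-terminus
        u1 = _unit(n.pos - c_prev.pos)
        u2 = _unit(n.pos - ca.pos)
        h_dir = _unit(u1 + u2)
        hp = n.pos + N_H_LENGTH_A * h_dir
        new.append(
            Atom(chain, resnum, resname, "H", "H", hp[0], hp[1], hp[2])
        )
    return s.with_atoms(new) if new else s


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("zero-length vector")
    return v / nrm


# ---------------------------------------------------------------------------
# Donor / acceptor enumeration
# ---------------------------------------------------------------------------

def enumerate_donors_acceptors(
    s: Structure,
) -> tuple[list[tuple[Atom, list[Atom]]], list[Atom]]:
    """List H-bond donors (heavy atom with attached hydrogens) and acceptors.

    Donors: backbone N–H (non-proline), Ser/Thr hydroxyl O, Asn/Gln
    side-chain amide N, Lys terminal N.  Acceptors: backbone carbonyl O
    and Ser/Thr/Asn/Gln side-chain oxygens.  Donors lacking an explicit
    hydrogen are returned with an empty hydrogen list; whether they are
    usable is decided at detection time (rotatable donors may be evaluated
    at the optimal H orientation).
    """
    donors: list[tuple[Atom, list[Atom]]] = []
    acceptors: list[Atom] = []
    for (chain, resnum), atoms in s.residues().items():
        resname = atoms[0].resname
        if resname not in THREE_LETTER:
            warnings.warn(f"unknown residue {resname} at {chain}/{resnum}; skipped")
            continue
        index = {a.name: a for a in atoms}
        if "N" in index and resname != "PRO":
            hs = [index[h] for h in ("H", "H1", "H2", "H3") if h in index]
            donors.append((index["N"], hs))
        if "O" in index:
            acceptors.append(index["O"])
        for heavy, hnames in SIDECHAIN_DONORS.get(resname, {}).items():
            if heavy in index:
                hs = [index[h] for h in hnames if h in index]
                donors.append((index[heavy], hs))
        for heavy in SIDECHAIN_ACCEPTORS.get(resname, ()):
            if heavy in index:
                acceptors.append(index[heavy])
    return donors, acceptors


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_hbonds(
    s: Structure,
    dmax_nm: float = DEFAULT_DMAX_NM,
    angle_max_deg: float = DEFAULT_ANGLE_MAX_DEG,
    allow_virtual_h: bool = True,
) -> list[HBond]:
    """Detect all donor–acceptor pairs satisfying the geometric criteria.

    A pair bonds when d(D, A) < ``dmax_nm`` and the angle A–D–H at the
    donor is < ``angle_max_deg`` for at least one hydrogen attached to the
    donor.  Same-residue backbone–backbone pairs and covalently bonded
    pairs (heavy-atom distance < 2 Å) are excluded.  Rotatable hydroxyl /
    ammonium donors without an explicit H are accepted at the orientation
    minimising the angle (i.e. the distance criterion decides) when
    ``allow_virtual_h`` is set; other donors without H are skipped with a
    warning.
    """
    if dmax_nm <= 0 or angle_max_deg <= 0:
        raise ValueError("cutoffs must be positive")
    donors, acceptors = enumerate_donors_acceptors(s)
    dmax_a = dmax_nm * 10.0
    bonds: list[HBond] = []
    for heavy, hs in donors:
        if not hs and not (allow_virtual_h and heavy.name in ROTATABLE_DONOR_ATOMS):
            warnings.warn(
                f"donor {heavy.chain}/{heavy.resnum}/{heavy.name} has no "
                "hydrogen; skipped"
            )
            continue
        for acc in acceptors:
            if heavy.key == acc.key:
                continue
            same_res = (heavy.chain, heavy.resnum) == (acc.chain, acc.resnum)
            if same_res and heavy.name in BACKBONE_ATOMS and acc.name in BACKBONE_ATOMS:
                continue
            d = float(np.linalg.norm(heavy.pos - acc.pos))
            if d >= dmax_a or d < COVALENT_CUTOFF_A:
                continue
            angle, hname = _best_angle(heavy, hs, acc)
            if angle < angle_max_deg:
                bonds.append(
                    HBond(
                        donor=(heavy.chain, heavy.resnum, heavy.resname, heavy.name),
                        hydrogen=hname,
                        acceptor=(acc.chain, acc.resnum, acc.resname, acc.name),
                        d_da_nm=d / 10.0,
                        angle_adh_deg=angle,
                    )
                )
    bonds.sort(key=lambda b: (b.donor[1], b.donor[3], b.acceptor[1], b.acceptor[3]))
    return bonds


def _best_angle(heavy: Atom, hs: list[Atom], acc: Atom) -> tuple[float, str | None]:
    """Smallest A–D–H angle over the donor's hydrogens (0° if rotatable-virtual)."""
    if not hs:
        return 0.0, None
    da = _unit(acc.pos - heavy.pos)
    best, best_name = math.inf, None
    for h in hs:
        dh = _unit(h.pos - heavy.pos)
        ang = math.degrees(math.acos(np.clip(np.dot(da, dh), -1.0, 1.0)))
        if ang < best:
            best, best_name = ang, h.name
    return best, best_name


# ---------------------------------------------------------------------------
# Region classification (latch report)
# ---------------------------------------------------------------------------

#: Residue-range map in the Cin8 numbering: the neck linker spans 516–528
#: with the N-latch at position 522; β7 anchors at 412/414; the loop
#: between α1 and β3 contributes 157; the cover strand is 73–75.
DEFAULT_REGION_MAP = {
    "nl_range": (516, 528),
    "latch_position": 522,
    "beta7_anchors": (412, 414),
    "alpha1_beta3_loop": (157,),
    "cover_strand": (73, 75),
}

REGION_LABELS = ("N-latch", "beta7-beta10", "intra-NL", "cover-strand", "other")


def latch_report(bonds: list[HBond], region_map: dict | None = None) -> LatchReport:
    """Classify NL/motor-domain bonds into regions and flag the conserved bond.

    The conserved bond is the backbone H-bond between the carbonyl O of the
    α1–β3 loop glycine (position 157) and the backbone N at the N-latch
    position (522), present in functional variants.
    """
    rm = dict(DEFAULT_REGION_MAP)
    if region_map:
        rm.update(region_map)
    nl_lo, nl_hi = rm["nl_range"]
    latch = rm["latch_position"]
    beta7 = set(rm["beta7_anchors"])
    loop = set(rm["alpha1_beta3_loop"])
    cs_lo, cs_hi = rm["cover_strand"]

    def in_nl(r: int) -> bool:
        return nl_lo <= r <= nl_hi

    counts = {k: 0 for k in REGION_LABELS}
    conserved = False
    for b in bonds:
        r1, a1 = b.donor[1], b.donor[3]
        r2, a2 = b.acceptor[1], b.acceptor[3]
        pair = {r1, r2}
        if (
            pair == {latch} | loop
            and {a1, a2} == {"N", "O"}
        ):
            conserved = True
        if latch in pair and (pair & (loop | beta7)):
            counts["N-latch"] += 1
        elif in_nl(r1) and in_nl(r2):
            counts["intra-NL"] += 1
        elif (pair & beta7) and any(in_nl(r) and r != latch for r in pair):
            counts["beta7-beta10"] += 1
        elif any(cs_lo <= r <= cs_hi for r in pair) and any(in_nl(r) for r in pair):
            counts["cover-strand"] += 1
        else:
            warnings.warn(f"bond {b.donor}–{b.acceptor} outside mapped regions")
            counts["other"] += 1
    return LatchReport(
        bonds=list(bonds),
        region_counts=counts,
        total=len(bonds),
        conserved_latch_bond=conserved,
    )
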