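"""Seeded generators for every input the analysis stages consume.

The generators emulate the study conditions of the single-molecule and
cell-imaging experiments: 90 s bleaching movies at 1 s intervals with
~45 a.u. GFP steps and ~23 s bleach lifetime; drift–diffusion motor
tracks with velocities of order 100 nm/s (minus-end negative);
microtubule-sliding events of each classification class (400 s movies at
10 s intervals); fields of line-like microtubules plus point motors at
known density; exponential OD growth; and synthetic coordinate fixtures
realizing specified donor–acceptor hydrogen-bond geometries.

Every generator takes an explicit integer seed and returns ground truth
alongside the data, so each downstream stage can be tested for parameter
recovery without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from skimage.draw import line as _draw_line
from scipy import ndimage

from .growth_stats import GrowthCurve
from .hbonds import (
    DEFAULT_ANGLE_MAX_DEG,
    DEFAULT_DMAX_NM,
    Atom,
    Structure,
    detect_hbonds,
)
from .imagequant import ImageField
from .motility import Track, TrackSet
from .photobleach import IntensityTrace
from .sliding import SlidingTrack, classify_sliding

__all__ = [
    "TraceSimParams",
    "TrackSimParams",
    "SceneSpec",
    "BondFixtureSpec",
    "GenerationError",
    "simulate_bleach_trace",
    "simulate_motor_tracks",
    "simulate_sliding_track",
    "render_field",
    "simulate_growth_curve",
    "build_hbond_fixture",
    "VARIANT_BOND_ARRAYS",
]


class GenerationError(RuntimeError):
    """A generator failed to realize the requested ground truth."""


# ---------------------------------------------------------------------------
# Photobleaching traces
# ---------------------------------------------------------------------------

@dataclass
class TraceSimParams:
    """Stationary-particle bleaching movie: 90 s at 1 s intervals by default."""

    n_traces: int = 100
    n_fluor: int = 4              # GFP per particle (homotetramer)
    unit_intensity: float = 45.0  # a.u. per fluorophore
    noise_sd: float = 8.0         # a.u.
    bleach_lifetime: float = 23.0  # s
    frame_interval: float = 1.0   # s
    duration: float = 90.0        # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fluor < 1:
            raise ValueError("n_fluor must be >= 1")
        if not self.unit_intensity > 0:
            raise ValueError("unit_intensity must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.bleach_lifetime > 0:
            raise ValueError("bleach_lifetime must be positive")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        if self.duration < self.frame_interval:
            raise ValueError("duration must be >= frame_interval")


def simulate_bleach_trace(
    params: TraceSimParams,
) -> tuple[list[IntensityTrace], list[dict]]:
    """Simulate staircase bleaching traces with per-fluorophore ground truth.

    Each fluorophore bleaches irreversibly at an exponential time with mean
    ``bleach_lifetime``; the trace is unit_intensity × (number still
    fluorescing) plus Gaussian noise.  Returns (traces, ground truth),
    where each ground-truth record lists the step times inside the movie
    and the (constant) step amplitude.
    """
    rng = np.random.default_rng(params.seed)
    times = np.arange(
        0.0, params.duration + params.frame_interval / 2, params.frame_interval
    )
    traces, truth = [], []
    for i in range(params.n_traces):
        bleach_times = np.sort(
            rng.exponential(params.bleach_lifetime, size=params.n_fluor)
        )
        alive = (times[None, :] < bleach_times[:, None]).sum(axis=0)
        y = alive * params.unit_intensity
        if params.noise_sd > 0:
            y = y + rng.normal(0.0, params.noise_sd, size=times.size)
        traces.append(IntensityTrace(f"particle_{i:05d}", times.copy(), y))
        truth.append(
            {
                "particle_id": f"particle_{i:05d}",
                "bleach_times_s": bleach_times.tolist(),
                "step_times_in_movie_s": bleach_times[
                    bleach_times <= params.duration
                ].tolist(),
                "step_amplitude_au": params.unit_intensity,
            }
        )
    return traces, truth


# ---------------------------------------------------------------------------
# Motor tracks (drift--diffusion)
# ---------------------------------------------------------------------------

@dataclass
class TrackSimParams:
    """Drift–diffusion model behind processive single-motor trajectories."""

    n_tracks: int = 100
    velocity: float = -318.0        # nm/s, minus-end negative
    diffusion_coeff: float = 2000.0  # nm^2/s
    detach_rate: float = 0.0        # 1/s; 0 = never detaches
    frame_interval: float = 1.0     # s
    duration: float = 90.0          # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be >= 0")
        if self.detach_rate < 0:
            raise ValueError("detach_rate must be >= 0")
        if not self.frame_interval > 0 or not self.duration > 0:
            raise ValueError("frame_interval and duration must be positive")


def simulate_motor_tracks(params: TrackSimParams) -> TrackSet:
    """Euler–Maruyama drift–diffusion tracks with exponential detachment.

    x(t+Δ) = x(t) + vΔ + N(0, 2DΔ); the track ends at its detach time
    (exponential with rate ``detach_rate``) or at ``duration``.  Ground
    truth (the generating parameters and per-track durations) is stored on
    the returned TrackSet.
    """
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval
    tracks = []
    durations = []
    for i in range(params.n_tracks):
        if params.detach_rate > 0:
            t_end = min(rng.exponential(1.0 / params.detach_rate), params.duration)
        else:
            t_end = params.duration
        n_steps = max(1, int(math.floor(t_end / dt)))
        steps = params.velocity * dt + rng.normal(
            0.0, math.sqrt(2.0 * params.diffusion_coeff * dt), size=n_steps
        )
        x = np.concatenate(([0.0], np.cumsum(steps)))
        t = np.arange(n_steps + 1) * dt
        tracks.append(Track(f"track_{i:05d}", t, x))
        durations.append(n_steps * dt)
    return TrackSet(
        tracks,
        ground_truth={
            "velocity_nm_s": params.velocity,
            "diffusion_coeff_nm2_s": params.diffusion_coeff,
            "detach_rate_per_s": params.detach_rate,
            "durations_s": durations,
        },
    )


# ---------------------------------------------------------------------------
# Sliding events
# ---------------------------------------------------------------------------

SLIDING_FRAME_INTERVAL_S = 10.0
SLIDING_DURATION_S = 400.0


def simulate_sliding_track(kind: str, seed: int) -> SlidingTrack:
    """Generate a sliding event of the requested classification class.

    Movies are 400 s at 10 s intervals.  The construction is re-checked
    with :func:`~motormetrics.sliding.classify_sliding` under default
    thresholds; a mismatch raises :class:`GenerationError` rather than
    silently returning an off-class track.
    """
    rng = np.random.default_rng(seed)
    n = int(SLIDING_DURATION_S / SLIDING_FRAME_INTERVAL_S)  # 40 steps
    t = np.arange(n + 1) * SLIDING_FRAME_INTERVAL_S
    jitter = rng.normal(0.0, 0.02, size=n + 1)

    if kind in ("directional_plus", "directional_minus"):
        v_um_per_frame = rng.uniform(0.04, 0.15)
        x = np.concatenate(([0.0], np.cumsum(np.full(n, v_um_per_frame))))
        if kind == "directional_minus":
            x = -x
    elif kind == "bidirectional":
        n1 = int(rng.integers(15, 26))
        amp1 = rng.uniform(1.0, 2.5)
        amp2 = rng.uniform(1.0, 2.5)
        seg1 = np.full(n1, amp1 / n1)
        seg2 = np.full(n - n1, -amp2 / (n - n1))
        x = np.concatenate(([0.0], np.cumsum(np.concatenate([seg1, seg2]))))
        if rng.random() < 0.5:
            x = -x
    elif kind == "static":
        x = 0.15 * np.sin(2 * math.pi * np.arange(n + 1) / n * rng.uniform(1, 3))
    else:
        raise ValueError(f"unknown sliding class {kind!r}")

    track = SlidingTrack(f"{kind}_{seed}", t, x + jitter)
    got = classify_sliding(track).label
    if got != kind:
        raise GenerationError(
            f"constructed track classifies as {got!r}, requested {kind!r}"
        )
    return track


# ---------------------------------------------------------------------------
# Image fields
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """A square observation field with microtubule segments and motor puncta."""

    field_area_um2: float = 346.0
    pixel_size_um: float = 0.1
    mt_segments: list = field(default_factory=list)   # [((x0,y0),(x1,y1)) µm]
    puncta: list = field(default_factory=list)        # [((x,y) µm, intensity a.u.)]
    psf_sigma_um: float = 0.15
    background: float = 10.0
    noise_sd: float = 0.0
    mt_intensity: float = 100.0

    def __post_init__(self) -> None:
        if not self.field_area_um2 > 0 or not self.pixel_size_um > 0:
            raise ValueError("field area and pixel size must be positive")
        side = math.sqrt(self.field_area_um2)
        for (p0, p1) in self.mt_segments:
            for (x, y) in (p0, p1):
                if not (0 <= x <= side and 0 <= y <= side):
                    raise ValueError("MT endpoint outside the field")
        for (pos, _inten) in self.puncta:
            if not (0 <= pos[0] <= side and 0 <= pos[1] <= side):
                raise ValueError("punctum outside the field")

    @property
    def side_px(self) -> int:
        return int(round(math.sqrt(self.field_area_um2) / self.pixel_size_um))


def render_field(scene: SceneSpec, seed: int = 0) -> tuple[ImageField, dict]:
    """Render a grayscale field: MT lines and puncta blurred by a Gaussian PSF.

    Returns (image, ground truth) where the ground truth holds the total
    microtubule length (µm) and the punctum count.
    """
    npx = scene.side_px
    if npx > 4096:
        raise ValueError(f"image would be {npx}^2 px (> 4096^2)")
    rng = np.random.default_rng(seed)
    canvas = np.zeros((npx, npx), dtype=float)
    total_len = 0.0
    for (x0, y0), (x1, y1) in scene.mt_segments:
        total_len += math.hypot(x1 - x0, y1 - y0)
        r0, c0 = _to_px(y0, x0, scene.pixel_size_um, npx)
        r1, c1 = _to_px(y1, x1, scene.pixel_size_um, npx)
        rr, cc = _draw_line(r0, c0, r1, c1)
        canvas[rr, cc] += scene.mt_intensity
    for (x, y), inten in scene.puncta:
        r, c = _to_px(y, x, scene.pixel_size_um, npx)
        canvas[r, c] += inten
    sigma_px = scene.psf_sigma_um / scene.pixel_size_um
    if sigma_px > 0 and canvas.any():
        peak = canvas.max()
        canvas = ndimage.gaussian_filter(canvas, sigma_px)
        # keep amplitudes comparable across PSF widths
        if canvas.max() > 0:
            canvas *= peak / canvas.max()
    img = canvas + scene.background
    if scene.noise_sd > 0:
        img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
    return (
        ImageField(img, scene.pixel_size_um),
        {"total_mt_length_um": total_len, "n_puncta": len(scene.puncta)},
    )


def _to_px(row_um: float, col_um: float, pixel_size: float, npx: int) -> tuple[int, int]:
    r = min(npx - 1, max(0, int(round(row_um / pixel_size))))
    c = min(npx - 1, max(0, int(round(col_um / pixel_size))))
    return r, c


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

def simulate_growth_curve(
    od0: float = 0.2,
    doubling_time_min: float = 152.0,
    noise_sd: float = 0.0,
    duration_min: float = 600.0,
    interval_min: float = 30.0,
    seed: int = 0,
) -> GrowthCurve:
    """Exponential OD600 growth with multiplicative Gaussian noise.

    OD(t) = od0 · 2^(t / doubling_time) × (1 + ε), ε ~ N(0, noise_sd).
    The wild-type default doubling time is 152 min.
    """
    if not od0 > 0 or not doubling_time_min > 0:
        raise ValueError("od0 and doubling time must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + interval_min / 2, interval_min)
    od = od0 * np.power(2.0, t / doubling_time_min)
    if noise_sd > 0:
        od = od * np.maximum(1.0 + rng.normal(0.0, noise_sd, size=t.size), 1e-3)
    return GrowthCurve(t, od, od0=od0)


# ---------------------------------------------------------------------------
# H-bond coordinate fixtures
# ---------------------------------------------------------------------------

#: Bond arrays of the docked neck-linker models of the Cin8 variants, as
#: (residue, residue name, atom) pairs.  These are the inputs for
#: geometric fixtures; the detector must recover exactly these sets.
VARIANT_BOND_ARRAYS: dict[str, list[tuple]] = {
    "wt_cin8": [
        ((412, "PHE", "O"), (524, "PHE", "N")),
        ((412, "PHE", "O"), (523, "SER", "OG")),
        ((524, "PHE", "N"), (523, "SER", "OG")),
        ((157, "GLY", "O"), (522, "GLY", "N")),
    ],
    "cin8_nl_eg5": [
        ((412, "PHE", "O"), (524, "LYS", "N")),
        ((157, "GLY", "O"), (522, "ASN", "ND2")),
        ((157, "GLY", "O"), (522, "ASN", "N")),
        ((414, "ILE", "O"), (522, "ASN", "ND2")),
    ],
    "cin8_g522n": [
        ((412, "PHE", "O"), (524, "PHE", "N")),
        ((157, "GLY", "O"), (522, "ASN", "N")),
    ],
    "cin8_nl_eg5_ng": [
        ((412, "PHE", "O"), (524, "LYS", "N")),
        ((157, "GLY", "O"), (522, "GLY", "N")),
    ],
    "cin8_nl_cut7": [
        ((157, "GLY", "O"), (522, "ASN", "N")),
    ],
    "cin8_nl_cut7_ng": [
        ((412, "PHE", "O"), (524, "LEU", "N")),
    ],
}


@dataclass
class BondFixtureSpec:
    """Donor–acceptor pairs to realize geometrically, plus decoys that must not bond."""

    bonds: list[tuple]            # [((resnum, resname, atom), (resnum, resname, atom))]
    decoys: list[tuple] = field(default_factory=list)
    dmax_nm: float = DEFAULT_DMAX_NM
    angle_max_deg: float = DEFAULT_ANGLE_MAX_DEG

    def __post_init__(self) -> None:
        def norm(pair):
            return frozenset((tuple(pair[0]), tuple(pair[1])))

        bset = {norm(p) for p in self.bonds}
        dset = {norm(p) for p in self.decoys}
        if bset & dset:
            raise ValueError("bonds and decoys overlap")


_DONOR_ATOMS = {
    "N": None,  # backbone (non-Pro)
    "ND2": "ASN",
    "NE2": "GLN",
    "NZ": "LYS",
    "OG": "SER",
    "OG1": "THR",
}
_ACCEPTOR_ATOMS = {"O", "OD1", "OE1", "OG", "OG1"}
_H_NAME = {"N": "H", "ND2": "HD21", "NE2": "HE21", "NZ": "HZ1", "OG": "HG", "OG1": "HG1"}

_BOND_TARGET_A = 2.9     # target donor-acceptor distance, Å
_ANGLE_TARGET_DEG = 25.0  # keep 5° inside the 30° criterion
_REPEL_A = 3.9           # keep non-bonded compatible pairs outside dmax
_ISLAND_SPACING_A = 30.0


def _can_donate(resname: str, atom: str) -> bool:
    if atom == "N":
        return resname != "PRO"
    return _DONOR_ATOMS.get(atom) == resname


def _can_accept(atom: str) -> bool:
    return atom in _ACCEPTOR_ATOMS


def _resolve_roles(pair) -> tuple[tuple, tuple]:
    """Decide which endpoint donates: backbone O never donates, N never accepts."""
    e1, e2 = tuple(pair[0]), tuple(pair[1])
    d1 = _can_donate(e1[1], e1[2])
    d2 = _can_donate(e2[1], e2[2])
    a1 = _can_accept(e1[2])
    a2 = _can_accept(e2[2])
    if d1 and not d2:
        donor, acc = e1, e2
    elif d2 and not d1:
        donor, acc = e2, e1
    elif d1 and d2:
        # both could donate (e.g. two hydroxyls): donor is the one that
        # cannot accept, else the first
        if not a1:
            donor, acc = e1, e2
        elif not a2:
            donor, acc = e2, e1
        else:
            donor, acc = e1, e2
    else:
        raise ValueError(f"pair {pair} has no possible donor")
    if not _can_accept(acc[2]):
        raise ValueError(f"pair {pair}: {acc} cannot accept")
    return donor, acc


def build_hbond_fixture(spec: BondFixtureSpec) -> Structure:
    """Construct synthetic coordinates realizing exactly the requested bonds.

    Atoms participating in bonds are laid out per connected component by a
    small least-squares relaxation (bond distances near 0.29 nm, donor
    cones within 25°, non-bonded donor/acceptor pairs pushed beyond the
    distance cutoff); every other residue atom is parked on a
    well-separated lattice.  Hydrogens are placed explicitly along each
    donor's acceptor bisector.  The result is verified with
    :func:`~motormetrics.hbonds.detect_hbonds`; any mismatch raises
    :class:`GenerationError` naming the offending pair.
    """
    directed = [_resolve_roles(p) for p in spec.bonds]
    bond_atoms: list[tuple] = []
    for d, a in directed:
        for e in (d, a):
            if e not in bond_atoms:
                bond_atoms.append(e)
    for p in spec.decoys:
        for e in (tuple(p[0]), tuple(p[1])):
            if e not in bond_atoms:
                bond_atoms.append(e)

    # connected components over bonds
    parent = {e: e for e in bond_atoms}

    def find(e):
        while parent[e] != e:
            parent[e] = parent[parent[e]]
            e = parent[e]
        return e

    for d, a in directed:
        parent[find(d)] = find(a)
    comps: dict[tuple, list[tuple]] = {}
    for e in bond_atoms:
        comps.setdefault(find(e), []).append(e)

    resnums = sorted({e[0] for e in bond_atoms})
    island = {
        rn: np.array([_ISLAND_SPACING_A * i, 0.0, 0.0])
        for i, rn in enumerate(resnums)
    }

    positions: dict[tuple, np.ndarray] = {}
    for ci, (_, members) in enumerate(sorted(comps.items(), key=lambda kv: kv[1][0])):
        comp_bonds = [(d, a) for d, a in directed if d in members]
        anchor = island[members[0][0]] + np.array([0.0, 10.0 * ci, 0.0])
        if len(members) == 1:
            positions[members[0]] = anchor
            continue
        positions.update(
            _layout_component(members, comp_bonds, anchor, spec, seed=ci)
        )

    # hydrogens along each donor's mean acceptor direction
    hydrogens: list[tuple] = []
    donor_accs: dict[tuple, list[tuple]] = {}
    for d, a in directed:
        donor_accs.setdefault(d, []).append(a)
    for d, accs in donor_accs.items():
        u = np.sum(
            [
                (positions[a] - positions[d])
                / np.linalg.norm(positions[a] - positions[d])
                for a in accs
            ],
            axis=0,
        )
        u = u / np.linalg.norm(u)
        hydrogens.append((d, _H_NAME[d[2]], positions[d] + 1.0 * u))

    atoms = []
    for (rn, resname, aname), pos in positions.items():
        elem = "O" if aname.startswith("O") else "N"
        atoms.append(Atom("A", rn, resname, aname, elem, *pos))
    for (rn, resname, _aname), hname, pos in hydrogens:
        atoms.append(Atom("A", rn, resname, hname, "H", *pos))
    # parked backbone fillers so residues are recognizable protein residues
    for i, rn in enumerate(resnums):
        resname = next(e[1] for e in bond_atoms if e[0] == rn)
        placed = {a.name for a in atoms if a.resnum == rn}
        base = island[rn] + np.array([0.0, 0.0, -15.0])
        for j, aname in enumerate(("N", "CA", "C", "O")):
            if aname in placed:
                continue
            pos = base + np.array([0.0, 5.0 * j, 0.0])
            elem = "C" if aname in ("CA", "C") else aname
            atoms.append(Atom("A", rn, resname, aname, elem, *pos))
            if aname == "N" and resname != "PRO":
                hp = pos + np.array([0.0, 0.0, 1.0])
                atoms.append(Atom("A", rn, resname, "H", "H", *hp))

    structure = Structure(atoms, source_id="synthetic bond fixture")
    _verify_fixture(structure, directed, spec)
    return structure


def _layout_component(
    members: list[tuple],
    comp_bonds: list[tuple],
    anchor: np.ndarray,
    spec: BondFixtureSpec,
    seed: int,
) -> dict[tuple, np.ndarray]:
    """Relax one bond component's coordinates by least squares."""
    rng = np.random.default_rng(1000 + seed)
    idx = {e: i for i, e in enumerate(members)}
    n = len(members)
    x0 = np.empty((n, 3))
    for i in range(n):
        ang = 2 * math.pi * i / n
        x0[i] = anchor + 3.0 * np.array(
            [math.cos(ang), math.sin(ang), 0.1 * rng.standard_normal()]
        )
    donor_accs: dict[tuple, list[tuple]] = {}
    for d, a in comp_bonds:
        donor_accs.setdefault(d, []).append(a)
    bond_set = {frozenset((d, a)) for d, a in comp_bonds}
    compat = [
        (e1, e2)
        for i, e1 in enumerate(members)
        for e2 in members[i + 1 :]
        if frozenset((e1, e2)) not in bond_set
        and (
            (_can_donate(e1[1], e1[2]) and _can_accept(e2[2]))
            or (_can_donate(e2[1], e2[2]) and _can_accept(e1[2]))
        )
    ]
    cos_limit = math.cos(math.radians(_ANGLE_TARGET_DEG))

    def residuals(flat: np.ndarray) -> np.ndarray:
        p = flat.reshape(n, 3)
        res = []
        for d, a in comp_bonds:
            res.append(2.0 * (np.linalg.norm(p[idx[d]] - p[idx[a]]) - _BOND_TARGET_A))
        for d, accs in donor_accs.items():
            if len(accs) < 2:
                continue
            dirs = [
                (p[idx[a]] - p[idx[d]]) / np.linalg.norm(p[idx[a]] - p[idx[d]])
                for a in accs
            ]
            u = np.sum(dirs, axis=0)
            u = u / np.linalg.norm(u)
            for v in dirs:
                res.append(5.0 * max(0.0, cos_limit - float(np.dot(u, v))))
        for e1, e2 in compat:
            d12 = np.linalg.norm(p[idx[e1]] - p[idx[e2]])
            res.append(2.0 * max(0.0, _REPEL_A - d12))
        res.extend(0.05 * (p.mean(axis=0) - anchor))
        return np.array(res)

    sol = optimize.least_squares(residuals, x0.ravel(), xtol=1e-12, ftol=1e-12)
    p = sol.x.reshape(n, 3)
    return {e: p[idx[e]] for e in members}


def _verify_fixture(structure: Structure, directed: list[tuple], spec: BondFixtureSpec) -> None:
    found = detect_hbonds(
        structure, dmax_nm=spec.dmax_nm, angle_max_deg=spec.angle_max_deg
    )
    found_set = {
        frozenset(((b.donor[1], b.donor[3]), (b.acceptor[1], b.acceptor[3])))
        for b in found
    }
    want_set = {
        frozenset(((d[0], d[2]), (a[0], a[2]))) for d, a in directed
    }
    if found_set != want_set:
        missing = want_set - found_set
        extra = found_set - want_set
        raise GenerationError(
            f"fixture does not realize the requested bonds; "
            f"missing={sorted(map(sorted, missing))} extra={sorted(map(sorted, extra))}"
        )
    for p in spec.decoys:
        key = frozenset(((p[0][0], p[0][2]), (p[1][0], p[1][2])))
        if key in found_set:
            raise GenerationError(f"decoy pair {p} forms a bond")
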