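# motormetrics

Quantitative analysis tools for single-molecule studies of bi-directional
kinesin-5 motors (such as *S. cerevisiae* Cin8), for researchers who
quantify motor motility, microtubule (MT) sliding, fluorescence images,
docked neck-linker structures, and cell-growth phenotypes from the same
experimental campaign.

The package implements the full analysis stack:

* **Photobleaching calibration** (`photobleach`) — change-point detection
  of single-GFP bleaching steps in 90 s intensity traces, calibration of
  the single-fluorophore unit intensity *u* (≈45 a.u. per GFP), and
  gating of single tetrameric motors by the rule *I* < 4·*u* (≈180 a.u.).
* **Mean-displacement velocity** (`motility`) — MD(t) = ⟨x(t₀+t) − x(t₀)⟩
  over tracks aligned on their own starts, velocity from the
  through-origin fit MD = v·t (minus-end directed motion gives v < 0),
  plus per-track run lengths.
* **MT-sliding classification** (`sliding`) — events are *directional*
  when |net displacement| > 0.64 µm with no opposite excursion that is
  both > 0.64 µm and > 30% of the moving time, *bi-directional* when
  excursions exceed 0.64 µm both ways and the main direction holds < 70%
  of the moving time, else *static*; plus-end velocities are continuous
  plus-direction displacement over its moving time.
* **Image quantitation** (`imagequant`) — Phansalkar local thresholding
  T = m(1 + p·e^(−qm) + k(s/r − 1)), connected-component particle
  analysis, localization area, motors per µm of MT skeleton, bundle
  intensities, spindle-length categories (monopolar / <2 µm / >2 µm),
  and a greedy nearest-neighbour particle linker.
* **H-bond geometry** (`hbonds`) — donor–H···acceptor detection with
  d(D,A) < 0.36 nm and angle(A–D–H) < 30°, amide-hydrogen placement, and
  neck-linker "latch" reports that flag the conserved G157↔522 backbone
  bond.
* **Growth & statistics** (`growth_stats`) — doubling time = ln 2 / slope
  of ln(OD_t/OD₀) vs t; KS normality screening; Box-Cox transformation;
  one-way ANOVA; Tukey all-pairwise comparisons; and Dunnett
  many-to-one comparisons, including the equicoordinate critical value
  c solving P(maxᵢ|Tᵢ| ≤ c) = 1 − α for the k-variate t distribution with
  correlation ½, computed by direct numerical integration.
* **Synthetic data** (`synthetic`) — seeded generators for every input
  (bleaching staircases, drift–diffusion tracks, sliding events of each
  class, rendered MT/puncta fields, exponential growth curves, and
  PDB-writable coordinate fixtures realizing prescribed bond arrays),
  always returning ground truth alongside the data.

## Worked example

Run the all-synthetic demo pipeline (simulate → calibrate → gate →
motility → sliding → imaging → H-bonds → growth statistics):

```bash
motormetrics run --seed 1 --out demo_out
```

With seed 1 the calibration stage detects 614 bleaching steps across 200
simulated traces and reports a unit intensity of 45.16 ± 0.28 (SEM) a.u.
— the single-GFP intensity — giving a single-molecule gate of
4 × 45.16 ≈ 180.6 a.u., and a fluorophore lifetime of 23.05 ± 0.82 s
from the censoring-corrected estimate over 789 bleach events.  The
motility stage fits the mean displacement of 100 drift–diffusion tracks
(true velocity −318 nm/s, D = 2000 nm²/s) and reports
v = −318.5 ± 0.7 nm/s.  The wild-type H-bond fixture yields exactly 4
bonds (1 N-latch, 2 β7–β10, 1 intra-NL) with the conserved latch bond
present.  The growth stage estimates doubling times of ≈151, ≈176 and
≈212 min for the three simulated strains (true values 152/175/210) and
Dunnett's test at α = 0.05 (critical value 2.86 at df = 6, k = 2) flags
both variants as significantly slower than the control.

The same stages are available as focused subcommands
(`motormetrics calibrate-steps --traces traces.csv`,
`motormetrics motility --tracks tracks.csv`,
`motormetrics hbond --pdb model.pdb --dmax 0.36`,
`motormetrics stats dunnett --input groups.csv --control wt`, …) and as
plain library calls.

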