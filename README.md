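# vepmap

Source mapping of motion-onset visual evoked potentials (VEPs) with
fMRI-seeded dipole constraints — plus the fMRI statistics that produce the
seeds: voxelwise Fourier analysis for phase-encoded retinotopy (including
visual field sign) and block-design GLM with permutation cluster inference.

The package is for electrophysiologists and neuroimagers who want a small,
fully tested, desk-scale implementation of the classic combined VEP/fMRI
localization workflow, and for methodologists who want its estimators
validated by parameter recovery on synthetic ground truth.

## The analysis

The motion-onset VEP is a sequence of named components: the striate **C1**
(peak ≈ 100 ms, polarity-inverted for upper vs. lower visual field),
**P120** over the motion-sensitive MT+ complex, the **N160/N180** complex
over posterior parietal and lateral occipital cortex, the broad **P250**
over the intraparietal sulcus, and an offset response **oC1** ≈ 100 ms after
motion stops, sharing the striate generator (fast motion adds an early
**N70** over MT+).

Each component is modeled by an equivalent current dipole fit over its
latency window by minimizing a compound cost

```
cost = 0.8 · RV + 0.2 · energy
```

where `RV` is the percent residual variance between the forward-modeled and
observed spatio-temporal scalp distribution under a concentric three-shell
spherical head model (analytic solution, radius 82 mm), and `energy`
penalizes mutually cancelling (interacting) source moments. Fitting is
*sequential* — dipoles explaining earlier waveform portions stay frozen as
later ones are added — and the fitted model is then *seeded*: each dipole is
snapped to the centroid of its nearest fMRI activation and refit in
orientation only. ROIs come from a 16 s ON/OFF block-design motion
experiment analyzed with a boxcar ⊗ canonical-HRF GLM and cluster-size
inference by sign-flip permutation; phase-encoded retinotopy (64 s/cycle,
8 cycles/scan) maps polar angle, eccentricity, and the visual field sign
used to delineate visual areas.

See `docs/methods.md` for the full model description, defaults, and
limitations.

## Worked example

The demonstration pipeline simulates a slow-motion VEP session (200 trials,
SNR 10, 8% artifact trials) and a matching block-design BOLD run, then runs
the complete workflow — preprocess → sequential fit → GLM → clusters → ROIs
→ seeding — and writes every report as text:

```bash
vepmap demo --seed 3 --out demo_out
```

prints (abridged):

```json
{
  "rejected_fraction": 0.055,
  "unseeded_total_rv_percent": 0.0266,
  "seeded_total_rv_percent": 0.0035,
  "peaks": {
    "C1":   {"latency_ms": 104.0, "amplitude_uv": -5.435, "channel": "O1"},
    "P120": {"latency_ms": 124.0, "amplitude_uv": 0.946,  "channel": "PO10"},
    "N160": {"latency_ms": 140.0, "amplitude_uv": -2.644, "channel": "P5"},
    "P250": {"latency_ms": 200.0, "amplitude_uv": 2.462,  "channel": "PO7"}
  },
  "n_clusters": 6,
  "matches": {"C1": "Calcarine", "P120": "MT+", "N160": "pIPS",
              "N180": "LOR", "P250": "IPS"}
}
```

Reading: 5.5% of trials were flagged by artifact rejection (8% injected,
some skipped where no epoch-exclusive window existed); the grand-average C1
peaks at 104 ms (one sample from the 100 ms truth) and is scalp-negative at
O1 for this upper-field stimulus; the unseeded five-dipole model already
leaves well under 1% of the 70–350 ms scalp variance unexplained; all six
simulated activations survive cluster thresholding; and nearest-ROI matching
assigns every dipole to its generating area, so the seeded model keeps RV
essentially at the noise floor. (The raw scalp peaks for N160/P250 land at
their window edges — at single channels the overlapping neighbors dominate;
the *source waveforms* of the seeded model peak at the correct latencies,
which is the model-based measurement the workflow relies on.) `demo_out/`
contains the dipole tables (TSV + JSON sidecar), ROI and match tables,
cluster table, rejection report and peak measures. Rerunning with the same
seed reproduces every file byte for byte.

The same steps are available piecemeal (`vepmap simulate vep`, `vepmap
preprocess`, `vepmap fit`, `vepmap glm`, `vepmap retino`, `vepmap
coregister`) and, of course, as library calls.

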