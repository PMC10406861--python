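# nucswap

Analysis of spontaneous histone H2A-H2B dimer exchange between
nucleosomes measured by three-color single-molecule FRET.

Nucleosomes are not static: they hand H2A-H2B dimers to one another upon
collision. The measurement mixes two nucleosome pools 1:1 — one
surface-immobilizable and labeled on DNA with a Cy3/Cy5 FRET pair, one
free in solution with Cy5.5 on H2B (labeling efficiency *F* = 0.537) —
and watches, molecule by molecule, for the FRET_Cy5.5 signature that
appears when an immobilized nucleosome acquires a labeled dimer. This
package implements the full analysis chain for that experiment, for
single-molecule biophysicists who want to simulate, validate, or re-run
it:

* **simulation** — a collision Monte Carlo of label exchange between
  individual nucleosomes, and a per-molecule trace synthesizer with
  photobleaching, acceptor cross-talk, background, and noise;
* **correction** — constant-background subtraction and inversion of the
  Cy5↔Cy5.5 channel-mixing system (leakage factors r₅ = 0.31,
  r₅.₅ = 0.27), giving per-frame efficiencies
  FRET_Cy5 = I₅/(I₃+I₅+I₅.₅) and FRET_Cy5.5 = I₅.₅/(I₃+I₅+I₅.₅);
* **classification** — photobleach step detection, single-molecule QC
  (lifetime > 10 s, SNR > 4, zero post-bleach intensity), red-excitation
  acceptor verification, FRET-signature species calls, and per-time-point
  censuses of distal-exchanged fractions;
* **kinetics** — the closed-form model of the countable distal fraction,

      f_e(t) = (F/2)(1 − F/2) · [1 − exp(−((1+F)/2) · k · C · t)]
             = 0.196 · [1 − exp(−0.77 · k · C · t)]   at F = 0.537,

  fitted by Levenberg–Marquardt to extract the bimolecular rate constant
  *k* (M⁻¹s⁻¹) at C = 400 nM, with standard errors, exchange timescales
  1/(k·C_ref) at a reference concentration, and
  difference-versus-sum-of-errors significance comparisons.

The stage boundaries follow scikit-learn conventions: `LeakageCorrector`
(fit/transform), `TraceClassifier` (predict/analyze), and
`ExchangeRateModel` (fit/predict, with fitted attributes `k_`, `k_se_`)
compose with sklearn tooling, and plain functions wrap each operation.

## Worked example

```python
import nucswap as ns

cfg = ns.RunConfig(
    scenario="unmod_low_salt",   # generate at the low-salt rate, k = 356
    design=ns.TimeCourseDesign(n_molecules_per_replicate=60,
                               n_replicates=4, seed=1),
)
report = ns.run_pipeline(cfg)
print(f"k = {report.fit.k_hat:.0f} +/- {report.fit.se_k:.0f} M^-1 s^-1")
print(f"timescale at 70 uM: {report.timescale_s:.0f} +/- {report.timescale_se_s:.0f} s")
print(f"QC pass: {report.n_qc_pass}/{report.n_traces}", report.class_counts)
print(report.census.round(4).to_string(index=False))
```

prints

```
k = 300 +/- 61 M^-1 s^-1
timescale at 70 uM: 48 +/- 10 s
QC pass: 1510/2160 {'intact': 1038, 'proximal_exchanged': 265, 'distal_exchanged': 190, 'ambiguous': 17}
 time_h  n_qualifying  n_distal  fraction     sd
    0.0           164         0    0.0000 0.0000
    1.0           155        10    0.0645 0.0608
    2.0           181        16    0.0884 0.0482
    4.0           168        26    0.1548 0.0783
    6.0           150        26    0.1733 0.0406
    8.0           172        31    0.1802 0.0477
   12.0           172        26    0.1512 0.0487
   18.0           166        23    0.1386 0.1112
   24.0           165        32    0.1939 0.0337
```

2,160 traces were synthesized at the low-salt rate constant
(356 M⁻¹s⁻¹), corrected, QC-filtered (70% pass; failures are mostly the
10 s lifetime gate), and classified; the distal-exchanged fraction rises
from 0 toward the combinatorial plateau 0.196, and the refitted rate
constant recovers the generating value within its standard error. The
timescale line converts *k* to the mean time per exchange event at the
70 μM nucleosome concentration of a human nucleus. See
`docs/methods.md` for the model, the defaults, and what the synthetic
data do and do not emulate.

The same run is available from a shell:

```bash
nucswap all --scenario unmod_low_salt --seed 1 --out runs/low_salt
nucswap simulate --seed 3 --out sim/          # or stage by stage
nucswap correct --traces sim/traces --r5 0.31 --r55 0.27 --out corr/
nucswap classify --traces corr/ --manifest sim/manifest.jsonl --out classified.csv
nucswap census --classified classified.csv --out census.csv
nucswap fit --census census.csv --F 0.537 --ctotal 4e-7 --out fit.json
nucswap compare --report fit_a.json --report fit_b.json
```

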