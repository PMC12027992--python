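# amidoqsar

QSAR analysis of amidino-substituted benzimidazole inhibitors of human
dipeptidyl peptidase III (DPP III), a zinc-dependent metallopeptidase
(family M49) linked to blood-pressure regulation, oxidative-stress defence
and several cancers.  The package is for cheminformaticians and medicinal
chemists who want a fully reproducible, tested version of the classic
"topological descriptors + GA-MLR + OECD validation battery" workflow on
this 36-compound inhibitor series — or on their own compounds.

## What it does

The 36 study compounds are 2-aryl benzimidazoles carrying one of three
amidine-type groups at position 5(6): unsubstituted amidine (group **a**,
12 compounds), 2-imidazolinyl (**b**, 13) or 1,4,5,6-tetrahydropyrimidin-2-yl
(**c**, 11).  All inhibit hDPP III at 30 µM; activity spans 0.1–100 %.

The modelling response is y = log₁₀(% inhibition).  The regression uses four
2D descriptors of the hydrogen-suppressed molecular graph:

* **Rww** — reciprocal hyper-detour index, Σ_{i<j} 1/(½(Δ²ᵢⱼ+Δᵢⱼ)) over the
  detour (longest-simple-path) matrix Δ;
* **Mats3e** — Moran autocorrelation of carbon-scaled Sanderson
  electronegativities at topological distance 3;
* **BELe4** — 4th lowest eigenvalue of the electronegativity-weighted
  Burden connectivity matrix;
* **nCs** — number of secondary sp³ carbons.

The published equation is

    log % inh. = −3.90 + 0.06·Rww + 1.25·Mats3e + 3.81·BELe4 − 0.94·nCs

Around the model the package implements the complete workflow: descriptor
pruning (constant / zero / |r| > 0.9 columns), activity-ranked 29/7
train–test splitting, genetic-algorithm k-subset selection with Q²_LOO
fitness (with an exhaustive-scan oracle), the validation battery (R²,
Q²_LOO/LMO, Y-scrambling, Q²_F1–F3, Lin's CCC, RMSE/MAE, Kxx/ΔK), the
leverage applicability domain (Williams plot, h\* = 3p′/n), inhibition-band
and occupancy statistics, IC₅₀ fitting by log-logistic regression, analogue
screening on the benzimidazole carbocycle, and seeded synthetic-data
generators for all of it.

## Worked example

```python
import amidoqsar as aq

study = aq.packaged_dataset()                    # 36 compounds, groups a/b/c
descriptors = aq.descriptor_table(study)         # Rww, Mats3e, BELe4, nCs

y = aq.log_transform([r.pct_inh_30uM for r in study])
split = aq.activity_ranked_split(y, seed=1)      # 29 train / 7 test
split.index = study.ids
ds = aq.build_dataset(study, descriptors, split=split)

model, report = aq.validate_model(ds, seed=1)
ad = aq.applicability_domain(model, ds)
```

Running `python examples/fit_and_validate.py` prints (abridged):

```
fitted equation:
  log(%inh) = 11.135 +0.058*Rww +2.131*Mats3e -12.438*BELe4 -0.555*nCs

  R2          0.4345
  Q2_LOO      0.2115
  R2_Yscr     0.1462
  Q2_Yscr    -0.2608
  CCC_ext     0.8731
  RMSE_ext    0.1390

applicability domain: h* = 0.517
  response outliers (|std CV residual| > 2): ['c5']
  outside structural domain (h > h*): none
```

Reading the numbers: the refit on this package's descriptor implementation
explains ~43 % of the log-activity variance on the training compounds (the
source study, using values from a proprietary descriptor engine, reported
82 %; see `docs/methods.md` for the analysis of this gap).  The Rww
coefficient (+0.058) essentially reproduces the published +0.06, and the
signs of all four coefficients match the published interpretation.  The
Y-scrambling means sit at the chance level (mean scrambled Q² < 0, mean
scrambled R² ≈ p/(n−1)), so whatever signal is fitted is not chance
correlation.  The warning leverage h\* = 3·5/29 = 0.517 reproduces the
published domain exactly: no compound exceeds it, and the
cyano/tetrahydropyrimidine compound **c5** is the single response outlier —
both findings of the original Williams-plot analysis.

The other example scripts each cover one capability:

| script | capability |
| --- | --- |
| `examples/activity_summary.py` | inhibition bands, ≥50 % counts, group occupancies |
| `examples/compute_descriptors.py` | descriptor table + CSV export |
| `examples/fit_and_validate.py` | split, refit, validation battery, applicability domain |
| `examples/screen_analogues.py` | OH/NH₂ analogues of the six most potent parents |
| `examples/simulate_recovery.py` | synthetic-data round trips (OLS, graphs, IC₅₀) |

## Data provenance

`amidoqsar/data/compounds.csv` transcribes the study activity table.  About
two thirds of the % inhibition values are quoted verbatim in the source
text and carry `pct_provenance=reported`; the remainder (mostly compounds
described only as "strong, ≥ 90 %", with IC₅₀ values) are reconstructed
from those qualitative statements and flagged `reconstructed`.  Structures
are neutral free bases drawn as the 5-substituted regioisomer with the
benzimidazole NH on N1 (one fixed, documented convention — topological
descriptors differ between the 5- and 6-substituted drawings).
Benzimidazole ring positions for analogue screening are numbered N1, C2,
N3, C3a, C4–C7, C7a; position 5 carries the amidine-type group, so C4, C6
and C7 are the free carbocyclic sites.

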