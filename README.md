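# indexweaver

Toolkit for building **evaluation index systems by expert consensus**:
Delphi panel statistics, two-round critical-value indicator screening,
AHP (analytic hierarchy process) weighting with consistency testing, and
hierarchical combination-weight aggregation — plus a synthetic panel
generator so every stage can be exercised and audited without raw expert
data.

It is aimed at health-services and policy researchers who run Delphi/AHP
studies (the classic "construct an indicator system, screen it over two
expert rounds, weight it by pairwise comparison" design) and want the
arithmetic, the thresholds, and the bookkeeping to be reproducible
instead of living in a spreadsheet.

## The methods in brief

**Delphi panel quality.** Response rate (returned/distributed); the
authority coefficient Cr = (Ca + Cs)/2 combining each expert's
judgment-basis coefficient Ca and familiarity Cs (Cr ≥ 0.7 ⇒
authoritative panel); and Kendall's coefficient of concordance

    W = 12 S / (m²(n³ − n) − m Σ T_e),   χ² = m(n − 1) W,

with midranks and the tie correction T_e = Σ(t³ − t), testing whether m
experts rank n indicators consistently.

**Two-round screening.** Per indicator: mean score, full-mark rate, and
coefficient of variation (CV = sd/mean). Level-wide critical values are
mean−SD (means), rate−SD (full-mark rates) and CV+SD (CVs) across the
indicators being screened. Round 1: fail all three → excluded; fail
exactly two → *inquiry item*, excluded when the agreed exclusion vote
rate exceeds 50%. Round 2: retain iff mean > 3.5 and CV < 0.25 (combined
with recomputed critical values). Every decision lands in an audit
ledger.

**AHP weighting.** Saaty judgment matrices (from expert pairwise input or
from per-indicator mean importance scores), priority weights as the
principal eigenvector, and the consistency ratio CR = CI/RI with
CI = (λmax − n)/(n − 1), accepted when CR < 0.1. Local weights multiply
down the tree into combination weights; leaf combination weights sum
to 1.

The package ships a reference fixture: a published three-level
doctor-evaluation index system for online medical platforms (3
dimensions, 8 sub-dimensions, 60 leaf indicators with local weights) and
its panel metadata, used throughout the tests as ground truth for
aggregation.

## Worked example

```sh
$ indexweaver fixture --out demo
wrote demo/hierarchy.json (71 nodes)
$ indexweaver aggregate --hierarchy demo/hierarchy.json --out demo
wrote weight table with 71 rows to demo
$ head -4 demo/weight_table.csv
id,label,level,local_weight,combination_weight
A1,System quality,1,0.5247,0.5247
B1,Type of doctors,2,0.75,0.393525
C1,The tier level of hospitals,3,0.1889,0.07433687250000001
```

The `B1` row says: "type of doctors" carries 75% of the weight within the
system-quality dimension, and 0.5247 × 0.75 = 0.3935 of the total — the
published combination weight. Library use mirrors the CLI:

```python
>>> from indexweaver import build_judgment_matrix, priority_weights
>>> m = build_judgment_matrix({"B7": 4.6, "B8": 4.1}, step=0.5)  # one Saaty grade apart
>>> r = priority_weights(m)
>>> r.weights, r.lambda_max, r.cr, r.consistent
(array([0.66666667, 0.33333333]), 2.0, 0.0, True)

>>> import numpy as np
>>> from indexweaver import kendalls_w
>>> kendalls_w(np.array([[5, 4, 3, 4], [5, 5, 3, 4], [4, 4, 2, 5]]))
ConcordanceResult(w=0.7037037037037037, chi2=6.333333333333334, df=3, p=0.09647232237962797)
```

Three experts ranking four indicators agree substantially (W = 0.70) but
the panel is too small for χ² significance at the 5% level — exactly why
Delphi studies use larger panels. A full synthetic run:

```sh
indexweaver simulate --seed 42 --out run     # 23-expert, 69-indicator panel
indexweaver stats --ratings run/ratings.csv --round 1 --out run
indexweaver screen --ratings run/ratings.csv --votes votes.csv --out run
indexweaver report --run run --out run       # collated JSON + text report
```

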