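# ngloc

Sequence-only prediction of protein subcellular localization with an
n-gram naive Bayes classifier — library and command-line tool, for
anyone who needs compartment assignments for protein sequences at
proteome scale without GO terms, text mining, or any annotation beyond
the sequence itself.

A protein sequence S is decomposed into its overlapping length-n
peptides (n-grams) g₁ … g_B, and each localization class L (cytoplasm,
nucleus, mitochondria, …) is scored

    log score(L) = log P(L) + Σᵢ log[ (c(gᵢ, L) + α) / (C(L) + α·V) ]

where c(g, L) are per-class training gram counts, C(L) their total,
P(L) the class prior, α a Lidstone smoothing constant and V the
smoothing vocabulary size.  Posteriors p(L|S) come from a log-sum-exp
normalization.  Each prediction carries a confidence score
CS = 100·p₁ and a multi-localization confidence score
MLCS = 100·(p₁+p₂)·(p₂/p₁); when MLCS ≥ 60 the call is reported as a
dual location such as `CYT/NUC`, the signature of proteins that shuttle
between compartments.

Four species profiles ship with the package: **animal** (11 classes,
default n = 7), **plant** (11 classes, n = 6), **gram_negative**
(5 classes, n = 6) and **gram_positive** (4 classes, n = 6).

The package also provides leave-one-out validation (per-class
precision / sensitivity / specificity / MCC plus overall accuracy),
confidence-score calibration tables by CS decile, and a synthetic-corpus
generator with controllable class separability so the whole pipeline can
be exercised and tested without downloading any data.

## Worked example (library)

The two-sequence hand corpus: class A trained on `AAAA`, class B on
`CCCC`, n = 2, α = 1.  The query `AA` contributes one gram; with
V = 3 and uniform empirical priors, P(AA|A) = (3+1)/(3+3) = 2/3 and
P(AA|B) = (0+1)/(3+3) = 1/6, so the posterior for A is 0.8:

```python
from ngloc import NgramModel, make_fixture

fx = make_fixture("tiny2")
model = NgramModel.train(fx.records, fx.profile, n=2, alpha=1.0)
pred = model.score("AA")
print(pred.posteriors, pred.cs, pred.mlcs, pred.call)
```

prints

```
{'A': 0.8, 'B': 0.19999999999999996} 80.0 24.999999999999993 A
```

CS = 80 (the top posterior × 100); MLCS = 100·(0.8+0.2)·(0.2/0.8) = 25,
well under the 60 threshold, so the call is the single location `A`.

## Worked example (command line)

```sh
ngloc simulate --fixture gramneg_like --seed 7 --out corpus.fa
ngloc train --species gram_negative --in corpus.fa --out model.ngl
ngloc predict --model model.ngl --in queries.fa
```

```
seq_id	call	loc1	cs1	loc2	cs2	loc3	cs3	mlcs	n_skipped
cyt_0000	CYT	CYT	100.00	EXC	0.00	OUT	0.00	0.00	0
cyt_0001	CYT	CYT	100.00	EXC	0.00	OUT	0.00	0.00	0
cyt_0002	CYT	CYT	100.00	EXC	0.00	OUT	0.00	0.00	0
```

Each row gives the final call (single or dual), the top three locations
with their confidence scores, the MLCS, and the number of sequence
windows skipped for non-canonical residues.  Leave-one-out validation of
the same corpus prints the class-wise table:

```
$ ngloc validate --species gram_negative --in corpus.fa
Code	Prec.	Sens.	Spec.	MCC
CYT	1.000	0.341	1.000	0.401
EXC	0.091	1.000	0.516	0.217
IN	1.000	0.857	1.000	0.908
OUT	1.000	1.000	1.000	1.000
PER	1.000	0.750	1.000	0.859
% Overall accuracy	55.38%
```

(65 sequences at default signal strength — small corpora are hard;
`ngloc benchmark` on the same input prints the CS-decile reliability
table showing exactly which confidence levels to trust.)

All options can also be given in an INI file (`--config run.ini`,
section `[ngloc]`); explicit flags win.

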