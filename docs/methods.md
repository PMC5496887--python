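# Methods

## The model

`lysvote` classifies lysine-centered peptide windows as enzyme substrate
sites. The working assumption is that substrate specificity for many
lysine-modifying enzymes (sirtuin-family deacetylases are the motivating
case) is carried less by the local sequence than by the functional context
of the substrate protein: its processes, compartments, molecular functions,
domains, and above all its interaction partners. The model therefore fuses:

- a one-hot encoding of the window (20 bits per position, alphabetical
  residue order `ACDEFGHIKLMNPQRSTVWY`; ambiguity codes X/B/Z/U/O encode as
  all-zero blocks and can never occupy the central position, which is
  lysine by construction), and
- one presence bit per *selected* annotation term of the parent protein.

Term selection is a per-source hypergeometric two-tail screen of the
substrate proteins against the background proteome. Both over- and
under-represented terms are eligible — the encoded bit is presence either
way, and the classifier learns the sign. The raw p is the smaller tail,
corrected by Bonferroni within the source (m = number of terms annotated to
at least one background protein in that source). PPI links are flattened to
the same shape by making each partner accession a term of the other,
keeping links at STRING-style combined score ≥ 400 (medium confidence) by
default.

The classifier is a voting ensemble of K RBF-kernel SVMs sharing the
positive set, each trained against its own 1:1 negative draw from the
background (all full-window lysine sites of non-substrate proteins, drawn
without replacement). A candidate is called positive at `votes >= cutoff`.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `L` | 21 | window length (central K ± 10); 11–21 supported, 21 performed best in sequence-length sweeps |
| `alpha` | 1e-2 | per-source Bonferroni-corrected significance threshold for term selection |
| `cap` | 100 | at most this many selected terms per source (smallest corrected p first; ties broken by raw p, then term id) |
| `K`, `cutoff` | 9, 5 | ensemble size and majority vote; `cutoff=9` gives a stringent low-FPR regime |
| `C`, `gamma` | 1.0, 1/dim | SVM cost and RBF width; the classical library defaults for this model family |
| `min_score` | 400 | STRING-like combined-score threshold for PPI links |
| `redundancy_threshold` | 0.70 | greedy ungapped-identity filter on positive windows (keep-first order); windows more than 70% identical to a kept one are dropped |
| `train_fraction`, `R` | 0.8, 100 | protein-level holdout fraction and repeat count in the harness |

Seed policy: every stochastic step takes an integer seed; member seeds are
derived from the master seed as the first K words of
`numpy.random.SeedSequence(master_seed)` folded into the signed-32-bit
range, so a trained bundle is reproducible bit-for-bit across platforms.

## Evaluation protocol and leakage

Sites of one protein share all functional bits, so any split that puts two
sites of the same protein on opposite sides of the train/test divide leaks
the functional signature of test items into training. The harness guards
this twice per repeat: (1) positives and the freshly drawn negatives are
split 4/5–1/5 **by protein**; (2) feature selection is re-run on the
training-fold positive proteins only. The test suite includes a deliberate
anti-pattern run (`leak_features=True`) showing that selecting features on
all positives inflates null-data MCC — the reason the safeguard exists.

Metrics are Sn, Sp and MCC from the held-out confusion counts; MCC is
defined as 0 when any margin of the confusion matrix is empty, while an
empty Sn/Sp margin is a hard error. Standard errors use the sample standard
deviation over repeats divided by √R. A repeat whose folds come out
single-class redraws its negatives up to 10 times, then fails loudly.
Reported percentages round half-up to two decimals. Proportion comparisons
between two candidate pools use the Yates-corrected Pearson chi-squared on
the 2×2 table (statistic clipped to 0 when |ad−bc| ≤ T/2), df = 1.

## The synthetic-data generator

`generate_fixture` emulates the statistical structure the method exploits,
not biological realism. Proteins are i.i.d. uniform over the 20 standard
residues (default 500 proteins of 200–400 residues). A subset (default 30)
are substrates with 1–4 modified lysines each, placed at least 10 residues
from the termini (forcing a lysine in when necessary), so every planted
site supports a full 21-mer. Five signal terms, spread across BP/CC/MF/
DOMAIN, are carried by substrates with probability 0.9 and by everything
else with 0.05; all other terms are uniform background carriage (0.05). A
designated non-substrate hub protein is linked to substrates at the same
elevated rate (score 900), over random background links — mirroring the
situation where interaction with the enzyme's own neighborhood is the
strongest single feature class. The sequence motif is **off by default**
(`seq_motif_strength=0`): the planted discriminative signal is purely
functional, which is the regime the method is designed for. `.null()`
produces the matched no-signal control. The truth table is written under a
separate `truth/` directory that no training code path reads.

What passing tests on these fixtures show: that the pipeline recovers a
planted protein-level signal, stays calibrated when there is none, and that
its statistical primitives are exact. What they cannot show: performance on
real proteomes, where annotation coverage is biased and incomplete, terms
are hierarchically correlated (no GO-DAG structure is simulated), windows
are compositionally non-uniform, and the positive sets are far noisier.

## Problem sizes used in the standard benchmarks

The bundled experiments (`lysvote.benchmarks`, also run by
`scripts/acceptance.py`) use R = 20 harness repeats for the
functional-benefit and null-calibration runs on the default fixture, and 10
master-seed pairs for the reproducibility experiment, which trains on 30 of
45 substrate proteins and predicts a candidate pool of the held-out
substrate proteins' sites plus 2,000 background sites — emulating a
proteome-wide screen whose candidate list contains unseen true substrates
among ordinary lysines.

## Design choices where the design was open

- **Terminal windows** are dropped, not padded (a `pad_char` option
  exists): padding interacts badly with the all-zero encoding of unknown
  residues.
- **Window similarity** is ungapped identity fraction with greedy
  keep-first filtering — deterministic and order-stable; no alignment-based
  redundancy (BLAST/CD-HIT) is attempted.
- **Bonferroni scope** is per-source, matching the per-source selection
  cap; a global correction is a one-line change for users who prefer it.
- **Overlap between two prediction runs** is the Jaccard index of the
  positively called site sets, in percent (100 when both are empty). The
  plausible alternative |A∩B|/min(|A|,|B|) reads higher; Jaccard is the
  symmetric, conservative choice.
- **One-hot residue order** is fixed alphabetically. Any fixed permutation
  of the bits yields an identical classifier, so only determinism matters.
- **Duplicate site rows** in input tables deduplicate with a warning;
  unknown proteins and non-lysine positions are hard errors.

## Known limitations

- On the strongly planted default fixture the two classes are nearly
  separable, so vote counts are bimodal and almost no candidate sits in the
  gray zone where member models disagree. Run-to-run overlap of a *single*
  model is consequently already ≥95%, leaving little headroom for the
  ensemble to demonstrate its stabilizing effect; on real, noisier data the
  single-model overlap is far lower and the benefit of voting is larger.
  The reproducibility benchmark reports both numbers rather than asserting
  a large gap.
- Sequence-only models on uninformative windows typically collapse to a
  constant prediction (MCC 0 by the zero-denominator convention) rather
  than hovering at small positive MCC as on real data, because the
  generator's windows carry no residual compositional signal.
- Only the kernel-SVM backend is provided; the member-classifier interface
  is pluggable but alternative backends (random forests, neural networks)
  are out of scope.
- No probability calibration, class weighting, or score-based AUC: the ROC
  here is vote-count-based by design.
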