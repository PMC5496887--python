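"""Evaluation: Sn/Sp/MCC, the protein-level repeated-holdout harness, and
proportion comparisons.

The harness reproduces the study protocol that makes functional features
honest to evaluate: because every site of a protein shares that protein's
annotation bits, sites must be split between training and testing *by
protein*, and the enrichment-based feature selection must be re-run inside
each training fold. Selecting features on all positives and then
cross-validating looks much better on null data — that is leakage, and the
test suite demonstrates it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .annotations import AnnotationTable
from .encoding import encode_set
from .ensemble import (
    DEFAULT_FEATURE_GROUPS,
    VotingEnsemble,
    make_svm,
    select_feature_space,
    vote_predict,
)
from .sequence import SiteSet, SiteWindow, filter_redundancy, window_identity


@dataclass(frozen=True)
class EvalCounts:
    """A confusion matrix: true/false positive/negative counts."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise ValueError("confusion matrix is empty")


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, specificity and Matthews correlation coefficient."""

    Sn: float
    Sp: float
    MCC: float


def compute_metrics(c: EvalCounts) -> Metrics:
    """Sn = TP/(TP+FN), Sp = TN/(TN+FP),
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)).

    MCC is defined as 0 when any margin of the confusion matrix is empty;
    Sn/Sp with an empty margin are a hard error naming the margin.
    """
    if c.TP + c.FN == 0:
        raise ValueError("Sn undefined: no positive examples (TP+FN == 0)")
    if c.TN + c.FP == 0:
        raise ValueError("Sp undefined: no negative examples (TN+FP == 0)")
    sn = c.TP / (c.TP + c.FN)
    sp = c.TN / (c.TN + c.FP)
    denom = math.sqrt(
        float(c.TP + c.FN) * (c.TN + c.FP) * (c.TP + c.FP) * (c.TN + c.FN)
    )
    mcc = 0.0 if denom == 0 else (c.TP * c.TN - c.FN * c.FP) / denom
    return Metrics(Sn=sn, Sp=sp, MCC=mcc)


def protein_level_split(
    sites: SiteSet,
    fraction: float = 0.8,
    seed: int | np.random.Generator = 0,
) -> tuple[SiteSet, SiteSet]:
    """Partition a site set by protein, never by site.

    Proteins are shuffled with ``seed`` and the first ``round(fraction * P)``
    (half-up, clamped so both sides are non-empty) go to training; every site
    follows its protein, so no protein appears on both sides.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    proteins = sorted(sites.protein_ids())
    if len(proteins) < 2:
        raise ValueError("protein-level split needs >= 2 distinct proteins")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = [proteins[i] for i in rng.permutation(len(proteins))]
    n_train = int(math.floor(fraction * len(proteins) + 0.5))
    n_train = min(max(n_train, 1), len(proteins) - 1)
    train_proteins = set(order[:n_train])
    train = sites.subset(train_proteins)
    test = sites.subset(set(order[n_train:]))
    return train, test


def _draw_negatives(
    background: SiteSet,
    size: int,
    rng: np.random.Generator,
    exclude_proteins: set[str] = frozenset(),
    redundancy_threshold: float | None = 0.70,
    avoid_windows: Sequence[str] = (),
) -> SiteSet:
    """Sample ``size`` background sites, optionally redundancy-filtered.

    Draws are without replacement from the background minus the excluded
    proteins; candidates more than ``redundancy_threshold`` identical to an
    already accepted window (or to ``avoid_windows``) are rejected and the
    draw continues until the quota is met or the pool is exhausted.
    """
    pool = [w for w in background if w.protein_id not in exclude_proteins]
    if len(pool) < size:
        raise ValueError(
            f"background pool ({len(pool)} sites after exclusions) smaller "
            f"than requested {size}"
        )
    order = rng.permutation(len(pool))
    picked: list[SiteWindow] = []
    kept_windows: list[str] = list(avoid_windows)
    for i in order:
        w = pool[int(i)]
        if redundancy_threshold is not None and any(
            window_identity(w.window, kw) > redundancy_threshold
            for kw in kept_windows
        ):
            continue
        picked.append(w)
        kept_windows.append(w.window)
        if len(picked) == size:
            break
    if len(picked) < size:
        raise ValueError(
            f"could only draw {len(picked)} non-redundant negatives of {size}"
        )
    return SiteSet(picked, background.L).relabel("negative")


@dataclass
class HarnessResult:
    """Per-repeat metrics plus their means and standard errors."""

    repeats: pd.DataFrame  # columns: repeat, TP, TN, FP, FN, Sn, Sp, MCC
    config: dict = field(default_factory=dict)

    @property
    def R(self) -> int:
        return len(self.repeats)

    def mean(self) -> dict[str, float]:
        return {m: float(self.repeats[m].mean()) for m in ("Sn", "Sp", "MCC")}

    def se(self) -> dict[str, float | None]:
        """Standard error sd/sqrt(R), sample sd (R-1 denominator); None at R=1."""
        if self.R < 2:
            return {m: None for m in ("Sn", "Sp", "MCC")}
        return {
            m: float(self.repeats[m].std(ddof=1) / math.sqrt(self.R))
            for m in ("Sn", "Sp", "MCC")
        }

    def summary(self) -> str:
        mean, se = self.mean(), self.se()
        lines = [f"repeated holdout evaluation: R={self.R}"]
        for k, v in sorted(self.config.items()):
            lines.append(f"  {k}: {v}")
        for m in ("Sn", "Sp", "MCC"):
            s = "-" if se[m] is None else f"{se[m]:.4f}"
            lines.append(f"  {m}: mean {mean[m]:.4f}  se {s}")
        return "\n".join(lines)

    def write(self, path) -> None:
        self.repeats.to_csv(path, sep="\t", index=False)


def run_harness(
    positives: SiteSet,
    background: SiteSet,
    tables: Mapping[str, AnnotationTable],
    *,
    feature_groups: Sequence[str] = DEFAULT_FEATURE_GROUPS,
    R: int = 100,
    train_fraction: float = 0.8,
    K: int = 1,
    cutoff: int | None = None,
    alpha: float = 1e-2,
    cap: int = 100,
    C: float = 1.0,
    gamma: str | float = "auto",
    redundancy_threshold: float | None = 0.70,
    seed: int = 0,
    max_redraws: int = 10,
    leak_features: bool = False,
) -> HarnessResult:
    """The repeated protein-level holdout evaluation.

    Each of the ``R`` repeats independently: draws a fresh 1:1 negative set
    from the background, splits positives and negatives ~``train_fraction``
    at protein level, re-selects the functional features using only the
    training-fold positive proteins, encodes, fits (a single SVM for K=1, a
    voting ensemble otherwise), and scores the held-out fold. Returned means
    and standard errors are over repeats.

    ``leak_features=True`` deliberately selects features on *all* positive
    proteins instead of the training fold — the anti-pattern the protein-
    level protocol exists to prevent; it is provided for demonstration and
    must not be used for real evaluation.

    A repeat whose folds end up single-class redraws its negatives, up to
    ``max_redraws`` times, then fails.
    """
    if len(positives) == 0:
        raise ValueError("positive site set is empty")
    if redundancy_threshold is not None:
        positives = filter_redundancy(positives, redundancy_threshold)
    pos = positives.relabel("positive")
    if cutoff is None:
        cutoff = K // 2 + 1
    universe = pos.protein_ids() | background.protein_ids()

    rows = []
    for r in range(R):
        rng = np.random.default_rng([seed, r])
        for attempt in range(max_redraws + 1):
            try:
                neg = _draw_negatives(
                    background, len(pos), rng,
                    redundancy_threshold=redundancy_threshold,
                )
                train_pos, test_pos = protein_level_split(pos, train_fraction, rng)
                train_neg, test_neg = protein_level_split(neg, train_fraction, rng)
                if min(len(train_pos), len(test_pos), len(train_neg), len(test_neg)) == 0:
                    raise ValueError("single-class fold")
                break
            except ValueError:
                if attempt == max_redraws:
                    raise ValueError(
                        f"repeat {r}: could not build two-class folds after "
                        f"{max_redraws} redraws"
                    )

        select_on = pos.protein_ids() if leak_features else train_pos.protein_ids()
        space, _ = select_feature_space(
            select_on, universe, tables, pos.L,
            feature_groups=feature_groups, alpha=alpha, cap=cap,
        )

        test_proteins = test_pos.protein_ids() | test_neg.protein_ids()
        members = []
        for m in range(K):
            if m == 0:
                m_neg = train_neg
            else:
                m_neg = _draw_negatives(
                    background, len(train_pos), rng,
                    exclude_proteins=test_proteins,
                    redundancy_threshold=redundancy_threshold,
                )
            train = SiteSet(list(train_pos) + list(m_neg), pos.L)
            mat = encode_set(train, tables, space)
            clf = make_svm(C=C, gamma=gamma)
            clf.fit(mat.X, mat.y)
            members.append(clf)

        test = SiteSet(list(test_pos) + list(test_neg), pos.L)
        mat_test = encode_set(test, tables, space, for_training=False)
        votes = np.zeros(len(test), dtype=np.int64)
        for clf in members:
            votes += (clf.predict(mat_test.X) == 1).astype(np.int64)
        call = votes >= cutoff
        truth = np.array([w.label == "positive" for w in test])
        counts = EvalCounts(
            TP=int(np.sum(call & truth)),
            TN=int(np.sum(~call & ~truth)),
            FP=int(np.sum(call & ~truth)),
            FN=int(np.sum(~call & truth)),
        )
        met = compute_metrics(counts)
        rows.append(
            {
                "repeat": r,
                "TP": counts.TP, "TN": counts.TN,
                "FP": counts.FP, "FN": counts.FN,
                "Sn": met.Sn, "Sp": met.Sp, "MCC": met.MCC,
            }
        )

    return HarnessResult(
        repeats=pd.DataFrame(rows),
        config={
            "L": pos.L,
            "feature_groups": list(feature_groups),
            "R": R,
            "train_fraction": train_fraction,
            "K": K,
            "cutoff": cutoff,
            "alpha": alpha,
            "cap": cap,
            "C": C,
            "gamma": gamma,
            "redundancy_threshold": redundancy_threshold,
            "seed": seed,
            "leak_features": leak_features,
        },
    )


def proportion_enrichment_test(
    hits_a: int, total_a: int, hits_b: int, total_b: int
) -> tuple[float, float]:
    """Pearson chi-squared with Yates' continuity correction on the 2x2 table
    ``[[hits_a, total_a - hits_a], [hits_b, total_b - hits_b]]``, df = 1.

    chi2 = T (|ad - bc| - T/2)^2 / ((a+b)(c+d)(a+c)(b+d)), clipped to 0 when
    |ad - bc| <= T/2; the p-value is the upper tail of the chi-squared
    distribution with one degree of freedom.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= hits_a <= total_a and 0 <= hits_b <= total_b):
        raise ValueError("hits must lie in [0, total]")
    a, b = hits_a, total_a - hits_a
    c, d = hits_b, total_b - hits_b
    T = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("chi-squared undefined: a margin of the 2x2 table is zero")
    diff = abs(a * d - b * c)
    if diff <= T / 2:
        stat = 0.0
    else:
        stat = T * (diff - T / 2) ** 2 / margins
    return float(stat), float(chi2_dist.sf(stat, df=1))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (30.795 -> 30.80)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ProportionSummary:
    """Predicted-positive proportions of two candidate sets plus their test."""

    frame: pd.DataFrame  # columns: set, predicted, total, percent
    chi2: float
    p_value: float
    test_error: str | None = None
    cutoff: int | None = None

    def text(self) -> str:
        lines = [f"prediction summary (vote cutoff {self.cutoff})"]
        for _, row in self.frame.iterrows():
            lines.append(
                f"  {row['set']}: {row['predicted']}/{row['total']} "
                f"predicted positive ({row['percent']:.2f}%)"
            )
        if self.test_error is not None:
            lines.append(f"  proportion test unavailable: {self.test_error}")
        else:
            lines.append(
                f"  Yates chi-squared = {self.chi2:.4g}, p = {self.p_value:.4g}"
            )
        return "\n".join(lines)


def predict_and_summarize(
    ensemble: VotingEnsemble,
    candidate_sites: SiteSet,
    tables: Mapping[str, AnnotationTable],
    comparison_sites: SiteSet,
    cutoff: int | None = None,
) -> ProportionSummary:
    """Predict two site sets and compare their positive-call proportions.

    Typical use: candidate sites are known modified lysines, comparison sites
    are random lysines; a substrate classifier should call a significantly
    larger fraction of the former. Percentages are rounded half-up to two
    decimals. Re-runnable at any vote cutoff.
    """
    cut = ensemble.cutoff if cutoff is None else cutoff
    rows = []
    counts = []
    for name, sites in (("candidate", candidate_sites), ("comparison", comparison_sites)):
        pred = vote_predict(ensemble, sites, tables, cutoff=cut)
        hits, total = int(pred["call"].sum()), len(pred)
        counts.append((hits, total))
        pct = round_half_up(100.0 * hits / total, 2) if total else 0.0
        rows.append({"set": name, "predicted": hits, "total": total, "percent": pct})
    (ha, ta), (hb, tb) = counts
    try:
        stat, p = proportion_enrichment_test(ha, ta, hb, tb)
        err = None
    except ValueError as exc:
        stat, p, err = float("nan"), float("nan"), str(exc)
    return ProportionSummary(
        frame=pd.DataFrame(rows), chi2=stat, p_value=p, test_error=err, cutoff=cut
    )
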