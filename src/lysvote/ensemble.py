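"""The voting ensemble: K kernel classifiers over resampled negative sets.

Negative training examples are drawn from the background (all lysine sites of
non-substrate proteins), which dwarfs the positive set; a single classifier's
predictions therefore depend visibly on which negatives it happened to see.
The ensemble trains K members on the same positives but independently drawn
1:1 negative sets and calls a site positive when at least ``cutoff`` members
vote positive — the default 5-of-9 trades off sensitivity and specificity,
while 9-of-9 gives a stringent, low-false-positive regime.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .annotations import (
    SOURCES,
    AnnotationTable,
    FeatureSpace,
    build_feature_space,
    enrich_terms,
    select_features,
)
from .encoding import encode_set
from .sequence import SiteSet

DEFAULT_FEATURE_GROUPS = ("seq",) + SOURCES


def derive_member_seeds(master_seed: int, K: int) -> list[int]:
    """Deterministic, platform-independent per-member seeds.

    The first K words of ``numpy.random.SeedSequence(master_seed)``'s output
    stream, folded into the signed-32-bit range.
    """
    state = np.random.SeedSequence(master_seed).generate_state(K, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def sample_negatives(background: SiteSet, size: int, seed: int) -> SiteSet:
    """Draw ``size`` background sites without replacement, labeled negative."""
    if size > len(background):
        raise ValueError(
            f"cannot draw {size} negatives from a background of {len(background)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(background), size=size, replace=False)
    return SiteSet([background[int(i)] for i in idx], background.L).relabel("negative")


def make_svm(C: float = 1.0, gamma: str | float = "auto") -> SVC:
    """The member classifier: RBF-kernel SVM, width 1/dimension by default."""
    return SVC(kernel="rbf", C=C, gamma=gamma)


def select_feature_space(
    positive_proteins: set[str],
    universe: set[str],
    tables: Mapping[str, AnnotationTable],
    L: int,
    feature_groups: Sequence[str] = DEFAULT_FEATURE_GROUPS,
    alpha: float = 1e-2,
    cap: int = 100,
) -> tuple[FeatureSpace, dict[str, pd.DataFrame]]:
    """Run per-source enrichment and assemble the feature space.

    ``feature_groups`` lists the blocks to include: ``seq`` plus any of the
    annotation sources. Returns the space and the full per-source enrichment
    tables (for reporting).
    """
    unknown = set(feature_groups) - ({"seq"} | set(SOURCES))
    if unknown:
        raise ValueError(f"unknown feature groups: {sorted(unknown)}")
    include_seq = "seq" in feature_groups
    func_sources = [s for s in SOURCES if s in feature_groups and s in tables]
    if not include_seq and not func_sources:
        raise ValueError("feature_groups must include 'seq' or >=1 annotation source")
    enrichments: dict[str, pd.DataFrame] = {}
    selections: dict[str, pd.DataFrame] = {}
    for src in func_sources:
        records = enrich_terms(positive_proteins, universe, tables[src])
        enrichments[src] = records
        selections[src] = select_features(records, alpha=alpha, cap=cap)
    space = build_feature_space(L, selections, include_seq=include_seq)
    if space.dimension == 0:
        raise ValueError(
            "empty feature space: no sequence block requested and no term "
            "passed selection"
        )
    return space, enrichments


@dataclass
class VotingEnsemble:
    """K fitted classifiers sharing one feature space, plus the vote cutoff."""

    members: list[SVC]
    K: int
    cutoff: int
    feature_space: FeatureSpace
    master_seed: int
    member_seeds: list[int]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) != self.K or len(self.member_seeds) != self.K:
            raise ValueError("member count does not match K")
        if not (0 <= self.cutoff <= self.K + 1):
            raise ValueError(f"cutoff {self.cutoff} outside [0, K+1]")

    def votes(self, X: np.ndarray) -> np.ndarray:
        """Number of members predicting positive for each row of X."""
        if X.shape[0] == 0:
            return np.zeros(0, dtype=np.int64)
        votes = np.zeros(X.shape[0], dtype=np.int64)
        for clf in self.members:
            votes += (clf.predict(X) == 1).astype(np.int64)
        return votes


def train_ensemble(
    positives: SiteSet,
    background: SiteSet,
    tables: Mapping[str, AnnotationTable],
    *,
    K: int = 9,
    cutoff: int = 5,
    feature_groups: Sequence[str] = DEFAULT_FEATURE_GROUPS,
    alpha: float = 1e-2,
    cap: int = 100,
    C: float = 1.0,
    gamma: str | float = "auto",
    seed: int = 0,
    feature_space: FeatureSpace | None = None,
) -> VotingEnsemble:
    """Fit the K-member voting ensemble.

    Feature selection runs once, on the full positive set against the whole
    proteome (the final-model regime; the evaluation harness instead
    re-selects inside every training fold). Each member then draws its own
    1:1 negative set from the background, without replacement, using a seed
    derived from ``seed``, and is fitted independently.

    Pass ``feature_space`` to skip selection and reuse a fixed layout.
    """
    if len(positives) == 0:
        raise ValueError("positive site set is empty")
    if len(background) <= len(positives):
        raise ValueError(
            f"background ({len(background)} sites) must be larger than the "
            f"positive set ({len(positives)})"
        )
    if positives.L != background.L:
        raise ValueError("positive and background window lengths differ")

    if feature_space is None:
        universe = positives.protein_ids() | background.protein_ids()
        feature_space, _ = select_feature_space(
            positives.protein_ids(), universe, tables, positives.L,
            feature_groups=feature_groups, alpha=alpha, cap=cap,
        )

    pos_labeled = positives.relabel("positive")
    member_seeds = derive_member_seeds(seed, K)
    members: list[SVC] = []
    for mseed in member_seeds:
        negs = sample_negatives(background, len(positives), mseed)
        train = SiteSet(list(pos_labeled) + list(negs), positives.L)
        mat = encode_set(train, tables, feature_space)
        if len(np.unique(mat.y)) < 2:
            raise ValueError("degenerate single-class training set")
        clf = make_svm(C=C, gamma=gamma)
        clf.fit(mat.X, mat.y)
        members.append(clf)

    return VotingEnsemble(
        members=members,
        K=K,
        cutoff=cutoff,
        feature_space=feature_space,
        master_seed=seed,
        member_seeds=member_seeds,
        config={
            "feature_groups": list(feature_groups),
            "alpha": alpha,
            "cap": cap,
            "C": C,
            "gamma": gamma,
        },
    )


def vote_predict(
    ensemble: VotingEnsemble,
    sites: SiteSet,
    tables: Mapping[str, AnnotationTable],
    cutoff: int | None = None,
) -> pd.DataFrame:
    """Predict each site: columns protein_id, position, window, votes, call."""
    if sites.L != ensemble.feature_space.L:
        raise ValueError(
            f"site window length {sites.L} does not match the model's "
            f"L={ensemble.feature_space.L}"
        )
    cut = ensemble.cutoff if cutoff is None else cutoff
    mat = encode_set(sites, tables, ensemble.feature_space, for_training=False)
    votes = ensemble.votes(mat.X)
    return pd.DataFrame(
        {
            "protein_id": [w.protein_id for w in sites],
            "position": [w.position for w in sites],
            "window": [w.window for w in sites],
            "votes": votes,
            "call": votes >= cut,
        }
    )


def vote_roc(
    ensemble: VotingEnsemble,
    labeled_sites: SiteSet,
    tables: Mapping[str, AnnotationTable],
) -> pd.DataFrame:
    """ROC points swept over the integer vote cutoff 0..K+1.

    Cutoff 0 calls everything positive, K+1 calls nothing, and both TPR and
    FPR are non-increasing in the cutoff because ``votes >= c+1`` implies
    ``votes >= c``.
    """
    labels = np.array([w.label for w in labeled_sites])
    n_pos = int((labels == "positive").sum())
    n_neg = int((labels == "negative").sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("vote ROC needs both positive and negative sites")
    mat = encode_set(labeled_sites, tables, ensemble.feature_space, for_training=False)
    votes = ensemble.votes(mat.X)
    rows = []
    for c in range(ensemble.K + 2):
        call = votes >= c
        tp = int(np.sum(call & (labels == "positive")))
        fp = int(np.sum(call & (labels == "negative")))
        rows.append({"cutoff": c, "fpr": fp / n_neg, "tpr": tp / n_pos})
    return pd.DataFrame(rows)


def reproducibility_overlap(pred_a: pd.DataFrame, pred_b: pd.DataFrame) -> float:
    """Jaccard overlap, in percent, of two runs' positively called sites.

    Both prediction tables must cover the same candidate sites. Returns 100.0
    when neither run calls anything positive.
    """
    sites_a = set(zip(pred_a["protein_id"], pred_a["position"]))
    sites_b = set(zip(pred_b["protein_id"], pred_b["position"]))
    if sites_a != sites_b:
        raise ValueError("prediction tables cover different candidate sites")
    pos_a = set(zip(pred_a.loc[pred_a["call"], "protein_id"],
                    pred_a.loc[pred_a["call"], "position"]))
    pos_b = set(zip(pred_b.loc[pred_b["call"], "protein_id"],
                    pred_b.loc[pred_b["call"], "position"]))
    union = pos_a | pos_b
    if not union:
        return 100.0
    return 100.0 * len(pos_a & pos_b) / len(union)


# --- model bundle (directory) serialization ---------------------------------

_MANIFEST = "manifest.json"
_SPACE = "feature_space.tsv"


def save_bundle(ensemble: VotingEnsemble, bundle_dir) -> None:
    """Write the ensemble as a directory: feature space, members, manifest."""
    d = Path(bundle_dir)
    d.mkdir(parents=True, exist_ok=True)
    ensemble.feature_space.save(d / _SPACE)
    for i, clf in enumerate(ensemble.members):
        with open(d / f"member_{i:02d}.pkl", "wb") as fh:
            pickle.dump(clf, fh, protocol=4)
    manifest = {
        "format": "lysvote-bundle-v1",
        "K": ensemble.K,
        "cutoff": ensemble.cutoff,
        "master_seed": ensemble.master_seed,
        "member_seeds": ensemble.member_seeds,
        "config": ensemble.config,
    }
    payload = json.dumps(manifest, sort_keys=True).encode()
    space_text = (d / _SPACE).read_bytes()
    manifest["config_hash"] = hashlib.sha256(payload + space_text).hexdigest()
    with open(d / _MANIFEST, "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_bundle(bundle_dir) -> VotingEnsemble:
    d = Path(bundle_dir)
    with open(d / _MANIFEST) as fh:
        manifest = json.load(fh)
    if manifest.get("format") != "lysvote-bundle-v1":
        raise ValueError(f"{bundle_dir} is not a lysvote model bundle")
    space = FeatureSpace.load(d / _SPACE)
    members = []
    for i in range(manifest["K"]):
        with open(d / f"member_{i:02d}.pkl", "rb") as fh:
            members.append(pickle.load(fh))
    return VotingEnsemble(
        members=members,
        K=manifest["K"],
        cutoff=manifest["cutoff"],
        feature_space=space,
        master_seed=manifest["master_seed"],
        member_seeds=list(manifest["member_seeds"]),
        config=manifest.get("config", {}),
    )
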