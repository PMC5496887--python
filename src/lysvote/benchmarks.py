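"""Standard synthetic benchmark experiments.

These functions bundle the package's headline self-checks into reproducible,
seedable experiments on generated fixtures:

* :func:`functional_benefit` — how much enrichment-selected functional
  features add over sequence-only classification (repeated protein-level
  holdout on the planted-signal fixture vs. its configuration).
* :func:`null_mcc` — calibration on a no-signal fixture, where mean MCC
  should sit near zero for any feature set.
* :func:`ensemble_stability` — run-to-run reproducibility of the positive
  call set for a single model versus the 9-model majority-vote ensemble.
* :func:`acetylome_proportion_comparison` — the 2x2 Yates chi-squared
  comparison of predicted-substrate proportions between two candidate pools.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .ensemble import DEFAULT_FEATURE_GROUPS, sample_negatives
from .evaluation import proportion_enrichment_test, round_half_up, run_harness
from .model import SubstrateVotingModel
from .sequence import SiteSet, build_background, extract_windows
from .synthetic import SynthConfig, SyntheticFixture, generate_fixture


def functional_benefit(
    config: SynthConfig | None = None,
    R: int = 20,
    seed: int = 0,
) -> dict[str, float]:
    """Mean MCC with sequence-only vs sequence+all-functional features.

    Runs the leakage-safe harness twice on the same planted-signal fixture
    (the default :class:`SynthConfig` conditions) and reports the means and
    their difference. The functional gain is the synthetic analogue of the
    jump a substrate classifier shows when protein-level annotation context
    is added to an uninformative sequence neighborhood.
    """
    config = config if config is not None else SynthConfig(seed=seed)
    fixture = generate_fixture(config)
    model = SubstrateVotingModel.from_fixture(fixture)
    res_seq = model.evaluate(R=R, seed=seed, feature_groups=("seq",))
    res_all = model.evaluate(R=R, seed=seed, feature_groups=DEFAULT_FEATURE_GROUPS)
    mcc_seq = res_seq.mean()["MCC"]
    mcc_all = res_all.mean()["MCC"]
    return {
        "mcc_seq_only": mcc_seq,
        "mcc_all_features": mcc_all,
        "mcc_gain": mcc_all - mcc_seq,
        "sn_all_features": res_all.mean()["Sn"],
        "sp_all_features": res_all.mean()["Sp"],
        "R": R,
    }


def null_mcc(
    config: SynthConfig | None = None,
    R: int = 20,
    seed: int = 0,
) -> dict[str, float]:
    """Mean MCC on the no-signal control fixture for both feature regimes."""
    config = (config if config is not None else SynthConfig(seed=seed)).null()
    fixture = generate_fixture(config)
    model = SubstrateVotingModel.from_fixture(fixture)
    res_seq = model.evaluate(R=R, seed=seed, feature_groups=("seq",))
    res_all = model.evaluate(R=R, seed=seed, feature_groups=DEFAULT_FEATURE_GROUPS)
    return {
        "null_mcc_seq_only": res_seq.mean()["MCC"],
        "null_mcc_all_features": res_all.mean()["MCC"],
        "R": R,
    }


def stability_candidates(
    fixture: SyntheticFixture,
    n_train_proteins: int = 30,
    n_background_candidates: int = 300,
    seed: int = 0,
) -> tuple[SiteSet, SiteSet, SiteSet]:
    """Split a fixture for the reproducibility experiment.

    Returns ``(training positives, background, candidates)``: the model
    trains on the sites of ``n_train_proteins`` substrate proteins and
    predicts a candidate pool made of the held-out substrate proteins' sites
    plus a random background sample — emulating a proteome-wide screen whose
    candidate list contains unseen true substrates among ordinary lysines.
    """
    positives = extract_windows(fixture.proteome, fixture.positives, fixture.config.L)
    proteins = sorted(positives.protein_ids())
    if len(proteins) <= n_train_proteins:
        raise ValueError(
            f"fixture has {len(proteins)} substrate proteins; need more than "
            f"{n_train_proteins} to hold some out"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(proteins))
    train_proteins = {proteins[i] for i in order[:n_train_proteins]}
    held = set(proteins) - train_proteins
    background = build_background(fixture.proteome, positives.protein_ids(),
                                  fixture.config.L)
    bg_sample = sample_negatives(
        background, n_background_candidates, int(rng.integers(2**31))
    ).relabel("unlabeled")
    candidates = SiteSet(
        list(positives.subset(held).relabel("unlabeled")) + list(bg_sample),
        positives.L,
    )
    return positives.subset(train_proteins), background, candidates


def ensemble_stability(
    config: SynthConfig | None = None,
    n_pairs: int = 10,
    n_train_proteins: int = 30,
    n_background_candidates: int = 2000,
    seed: int = 0,
) -> dict[str, float]:
    """Mean positive-call overlap between independently seeded runs.

    For each of ``n_pairs`` master-seed pairs, trains two models with
    different seeds (hence different member negative sets) and measures the
    Jaccard overlap of their positive calls on the candidate pool — once for
    a single classifier (K=1, cutoff 1) and once for the 9-model
    majority-vote ensemble (cutoff 5). Voting should make the call set more
    reproducible.
    """
    from .ensemble import reproducibility_overlap

    config = config if config is not None else replace(
        SynthConfig(seed=seed), n_substrate_proteins=45
    )
    fixture = generate_fixture(config)
    train_pos, background, candidates = stability_candidates(
        fixture,
        n_train_proteins=n_train_proteins,
        n_background_candidates=n_background_candidates,
        seed=seed,
    )
    tables = SubstrateVotingModel.from_fixture(fixture).tables
    overlaps: dict[int, list[float]] = {1: [], 9: []}
    for K, cutoff in ((1, 1), (9, 5)):
        model = SubstrateVotingModel(
            train_pos, background, tables, K=K, cutoff=cutoff
        )
        for pair in range(n_pairs):
            s1, s2 = seed + 1000 + 2 * pair, seed + 1001 + 2 * pair
            pred_a = model.fit(seed=s1).predict(candidates)
            pred_b = model.fit(seed=s2).predict(candidates)
            overlaps[K].append(reproducibility_overlap(pred_a, pred_b))
    mean1 = float(np.mean(overlaps[1]))
    mean9 = float(np.mean(overlaps[9]))
    return {
        "overlap_k1_cutoff1": mean1,
        "overlap_k9_cutoff5": mean9,
        "overlap_gain": mean9 - mean1,
        "n_pairs": n_pairs,
    }


def acetylome_proportion_comparison(
    hits_a: int = 5412, total_a: int = 17572,
    hits_b: int = 3112, total_b: int = 19949,
) -> dict[str, float]:
    """Yates chi-squared comparison of two predicted-positive proportions.

    Defaults are the published proteome-wide screen counts: predicted
    substrates among known acetylation sites versus among random lysine
    sites; the difference is overwhelmingly significant.
    """
    stat, p = proportion_enrichment_test(hits_a, total_a, hits_b, total_b)
    return {
        "percent_a": round_half_up(100.0 * hits_a / total_a, 2),
        "percent_b": round_half_up(100.0 * hits_b / total_b, 2),
        "chi2": stat,
        "p_value": p,
    }
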