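"""Model/Results surface tying the pipeline together.

:class:`SubstrateVotingModel` is built from data (site windows, a background
site universe, annotation tables) or directly from files or a synthetic
fixture; ``fit()`` returns :class:`SubstrateVotingResults`, which carries the
fitted voting ensemble and exposes prediction, the vote-ROC, proportion
summaries, serialization and a text summary. Repeated-holdout evaluation
(:meth:`SubstrateVotingModel.evaluate`) works on the unfitted model, since it
refits inside every repeat.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .annotations import AnnotationTable, read_annotation_tsv, read_ppi_tsv, ppi_to_annotation
from .ensemble import (
    DEFAULT_FEATURE_GROUPS,
    VotingEnsemble,
    load_bundle,
    save_bundle,
    train_ensemble,
    vote_predict,
    vote_roc,
)
from .evaluation import (
    HarnessResult,
    ProportionSummary,
    predict_and_summarize,
    run_harness,
)
from .sequence import (
    SiteSet,
    build_background,
    extract_windows,
    filter_redundancy,
    read_fasta,
    read_site_table,
)


class SubstrateVotingModel:
    """Substrate-site predictor: one-hot windows + enrichment-selected
    functional bits, fitted as a K-member SVM voting ensemble.

    Parameters
    ----------
    positives : SiteSet
        Known substrate-site windows (redundancy-filtered on construction
        unless ``redundancy_threshold`` is None).
    background : SiteSet
        All candidate lysine windows of non-substrate proteins; the
        negative-sampling universe.
    tables : mapping of source name to AnnotationTable
        Functional annotations (any of BP, CC, MF, DOMAIN, PPI).
    K, cutoff : int
        Ensemble size and the vote count required for a positive call.
    feature_groups : sequence of str
        Feature blocks to use: ``"seq"`` and/or annotation source names.
    alpha, cap : float, int
        Per-source Bonferroni significance threshold and maximum number of
        selected terms.
    C, gamma : SVM cost and RBF kernel width (``"auto"`` = 1/dimension).
    """

    def __init__(
        self,
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
        redundancy_threshold: float | None = 0.70,
    ) -> None:
        if redundancy_threshold is not None:
            positives = filter_redundancy(positives, redundancy_threshold)
        self.positives = positives.relabel("positive")
        self.background = background
        self.tables = dict(tables)
        self.K = K
        self.cutoff = cutoff
        self.feature_groups = tuple(feature_groups)
        self.alpha = alpha
        self.cap = cap
        self.C = C
        self.gamma = gamma
        self.redundancy_threshold = redundancy_threshold
        self.proteome: dict[str, str] | None = None  # set by from_files/from_fixture

    # -- constructors --------------------------------------------------

    @classmethod
    def from_files(
        cls,
        proteome_fasta,
        positives_tsv,
        annotations_tsv=None,
        ppi_tsv=None,
        *,
        L: int = 21,
        min_score: float = 400,
        **kwargs,
    ) -> "SubstrateVotingModel":
        """Build from the on-disk formats: FASTA proteome, TSV site table,
        TSV annotations, TSV PPI links."""
        proteome = read_fasta(proteome_fasta)
        site_df = read_site_table(positives_tsv)
        positives = extract_windows(proteome, site_df, L, label="positive")
        background = build_background(proteome, positives.protein_ids(), L)
        tables: dict[str, AnnotationTable] = {}
        if annotations_tsv is not None:
            tables.update(read_annotation_tsv(annotations_tsv))
        if ppi_tsv is not None:
            tables["PPI"] = ppi_to_annotation(read_ppi_tsv(ppi_tsv), min_score)
        model = cls(positives, background, tables, **kwargs)
        model.proteome = proteome
        return model

    @classmethod
    def from_fixture(cls, fixture, *, L: int = 21, min_score: float = 400, **kwargs):
        """Build from an in-memory :class:`~lysvote.synthetic.SyntheticFixture`."""
        positives = extract_windows(
            fixture.proteome, fixture.positives, L, label="positive"
        )
        background = build_background(fixture.proteome, positives.protein_ids(), L)
        tables = dict(fixture.tables)
        if len(fixture.ppi_links):
            tables["PPI"] = ppi_to_annotation(fixture.ppi_links, min_score)
        model = cls(positives, background, tables, **kwargs)
        model.proteome = fixture.proteome
        return model

    # -- site helpers ---------------------------------------------------

    def windows_for(self, site_table: pd.DataFrame) -> SiteSet:
        """Extract windows for a candidate-site table against the stored proteome."""
        if self.proteome is None:
            raise ValueError(
                "model was built without a proteome; construct with "
                "from_files/from_fixture or extract windows yourself"
            )
        return extract_windows(
            self.proteome, site_table, self.positives.L, label="unlabeled"
        )

    # -- fitting and evaluation -----------------------------------------

    def fit(self, seed: int = 0) -> "SubstrateVotingResults":
        """Fit the voting ensemble (features selected on all positives)."""
        ensemble = train_ensemble(
            self.positives,
            self.background,
            self.tables,
            K=self.K,
            cutoff=self.cutoff,
            feature_groups=self.feature_groups,
            alpha=self.alpha,
            cap=self.cap,
            C=self.C,
            gamma=self.gamma,
            seed=seed,
        )
        return SubstrateVotingResults(self, ensemble)

    def evaluate(
        self,
        R: int = 100,
        seed: int = 0,
        *,
        feature_groups: Sequence[str] | None = None,
        K: int = 1,
        cutoff: int | None = None,
        **kwargs,
    ) -> HarnessResult:
        """Leakage-safe repeated protein-level holdout (see
        :func:`lysvote.evaluation.run_harness`); refits in every repeat."""
        return run_harness(
            self.positives,
            self.background,
            self.tables,
            feature_groups=self.feature_groups if feature_groups is None else feature_groups,
            R=R,
            K=K,
            cutoff=cutoff,
            alpha=self.alpha,
            cap=self.cap,
            C=self.C,
            gamma=self.gamma,
            redundancy_threshold=None,  # model already filtered its positives
            seed=seed,
            **kwargs,
        )


class SubstrateVotingResults:
    """A fitted voting ensemble plus the model that produced it."""

    def __init__(self, model: SubstrateVotingModel, ensemble: VotingEnsemble) -> None:
        self.model = model
        self.ensemble = ensemble

    @property
    def feature_space(self):
        return self.ensemble.feature_space

    def predict(
        self, sites: SiteSet | pd.DataFrame, cutoff: int | None = None
    ) -> pd.DataFrame:
        """Votes and calls per site; accepts a SiteSet or a site table."""
        if isinstance(sites, pd.DataFrame):
            sites = self.model.windows_for(sites)
        return vote_predict(self.ensemble, sites, self.model.tables, cutoff=cutoff)

    def vote_roc(self, labeled_sites: SiteSet) -> pd.DataFrame:
        return vote_roc(self.ensemble, labeled_sites, self.model.tables)

    def summarize(
        self,
        candidate_sites: SiteSet | pd.DataFrame,
        comparison_sites: SiteSet | pd.DataFrame,
        cutoff: int | None = None,
    ) -> ProportionSummary:
        if isinstance(candidate_sites, pd.DataFrame):
            candidate_sites = self.model.windows_for(candidate_sites)
        if isinstance(comparison_sites, pd.DataFrame):
            comparison_sites = self.model.windows_for(comparison_sites)
        return predict_and_summarize(
            self.ensemble, candidate_sites, self.model.tables,
            comparison_sites, cutoff=cutoff,
        )

    def save(self, bundle_dir) -> None:
        save_bundle(self.ensemble, bundle_dir)

    def summary(self) -> str:
        e = self.ensemble
        fs = e.feature_space
        lines = [
            "Substrate voting-ensemble model",
            "===============================",
            f"members (K):          {e.K}",
            f"vote cutoff:          {e.cutoff}",
            f"window length L:      {fs.L}",
            f"sequence bits:        {20 * fs.L if fs.include_seq else 0}",
            f"functional bits:      {fs.n_functional}",
            f"total dimension:      {fs.dimension}",
            f"positives (windows):  {len(self.model.positives)}",
            f"background sites:     {len(self.model.background)}",
            f"master seed:          {e.master_seed}",
            f"member seeds:         {e.member_seeds}",
        ]
        by_src = fs.counts_by_source()
        if by_src:
            lines.append("selected terms by source:")
            for src, cnt in sorted(by_src.items()):
                lines.append(f"  {src:7s} {cnt}")
        return "\n".join(lines)


def load_results(bundle_dir, model: SubstrateVotingModel) -> SubstrateVotingResults:
    """Reload a saved bundle against a model carrying the same data context."""
    return SubstrateVotingResults(model, load_bundle(bundle_dir))
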