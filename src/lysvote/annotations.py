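"""Functional annotations, hypergeometric enrichment, and feature selection.

Five annotation sources are supported: GO Biological Process (``BP``),
Cellular Component (``CC``), Molecular Function (``MF``), protein domains
(``DOMAIN``), and protein-protein interaction partners (``PPI``). Each source
maps proteins to flat term sets; a PPI links table is converted to the same
shape by treating each partner accession as a term of the other.

Terms that are over- or under-represented among the substrate proteins,
relative to a background proteome, are selected as binary classifier features
(hypergeometric test, Bonferroni-corrected per source, p < 1e-2, capped at the
100 most significant terms per source).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

SOURCES = ("BP", "CC", "MF", "DOMAIN", "PPI")

#: spreadsheet order of the enrichment table
ENRICH_COLUMNS = [
    "source", "term", "k", "n", "K", "N", "direction", "p_raw", "p_corrected",
]


@dataclass
class AnnotationTable:
    """Per-source mapping from protein accession to its term set.

    A protein absent from the mapping simply has no annotations in this
    source; it contributes zero to every enrichment count and receives
    all-zero feature bits.
    """

    source: str
    protein_to_terms: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.protein_to_terms = {
            p: frozenset(ts) for p, ts in self.protein_to_terms.items()
        }
        for p, ts in self.protein_to_terms.items():
            if any(not t for t in ts):
                raise ValueError(f"empty term id for protein {p!r}")

    def terms_of(self, protein: str) -> frozenset[str]:
        return self.protein_to_terms.get(protein, frozenset())

    def terms_in(self, proteins: Iterable[str]) -> set[str]:
        """Union of terms carried by the given proteins."""
        out: set[str] = set()
        for p in proteins:
            out |= self.protein_to_terms.get(p, frozenset())
        return out


def read_annotation_tsv(path) -> dict[str, AnnotationTable]:
    """Read a headered TSV (`protein_id`, `source`, `term_id`) into per-source tables."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"protein_id", "source", "term_id"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path} missing columns {sorted(missing)}")
    bad = set(df["source"]) - set(SOURCES)
    if bad:
        raise ValueError(f"unknown annotation sources in {path}: {sorted(bad)}")
    tables: dict[str, AnnotationTable] = {}
    for source, sub in df.groupby("source"):
        mapping: dict[str, set[str]] = {}
        for pid, term in zip(sub["protein_id"], sub["term_id"]):
            mapping.setdefault(pid, set()).add(term)
        tables[source] = AnnotationTable(source, {p: frozenset(t) for p, t in mapping.items()})
    return tables


def write_annotation_tsv(tables: Mapping[str, AnnotationTable], path) -> None:
    rows = [
        (p, src, t)
        for src in sorted(tables)
        for p in sorted(tables[src].protein_to_terms)
        for t in sorted(tables[src].protein_to_terms[p])
    ]
    pd.DataFrame(rows, columns=["protein_id", "source", "term_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_ppi_tsv(path) -> pd.DataFrame:
    """Read a STRING-like links TSV (`protein_a`, `protein_b`, `score`)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    missing = {"protein_a", "protein_b", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"PPI table {path} missing columns {sorted(missing)}")
    bad = df.index[pd.to_numeric(df["score"], errors="coerce").isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(
            f"non-numeric PPI score at line {int(bad[0]) + 2} of {path}"
        )
    df["score"] = pd.to_numeric(df["score"])
    return df


def ppi_to_annotation(links: pd.DataFrame, min_score: float = 400) -> AnnotationTable:
    """Turn a links table into a PPI annotation table.

    For every link at or above ``min_score`` each partner's accession becomes
    a term of the other, symmetrically; duplicate and reversed rows collapse.
    The default cutoff 400 is STRING's conventional medium-confidence score.
    """
    mapping: dict[str, set[str]] = {}
    for a, b, s in zip(links["protein_a"], links["protein_b"], links["score"]):
        if float(s) >= min_score and a != b:
            mapping.setdefault(str(a), set()).add(str(b))
            mapping.setdefault(str(b), set()).add(str(a))
    return AnnotationTable("PPI", {p: frozenset(t) for p, t in mapping.items()})


def hypergeometric_test(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """Over- and under-representation tail probabilities.

    With ``X ~ Hypergeometric(N, K, n)`` — drawing ``n`` proteins from a
    background of ``N`` of which ``K`` carry the term — returns
    ``(P(X >= k), P(X <= k))`` for the observed count ``k`` among positives.
    """
    if not (0 <= k <= n <= N):
        raise ValueError(f"require 0 <= k <= n <= N, got k={k} n={n} N={N}")
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N, got K={K} N={N}")
    if k > K:
        raise ValueError(f"observed k={k} exceeds background carriers K={K}")
    dist = hypergeom(N, K, n)
    p_over = float(dist.sf(k - 1))
    p_under = float(dist.cdf(k))
    return min(p_over, 1.0), min(p_under, 1.0)


def enrich_terms(
    positives: set[str],
    background: set[str],
    table: AnnotationTable,
) -> pd.DataFrame:
    """Hypergeometric enrichment of one source's terms in the positive proteins.

    Every term annotated to at least one background protein is tested. For
    each, ``direction`` is the smaller tail (``over`` if ``p_over <=
    p_under``), ``p_raw = min(p_over, p_under)`` and ``p_corrected`` is the
    Bonferroni correction by the number of terms tested in this source.

    Results are sorted by ``(p_corrected, p_raw, term)`` so the output is
    invariant to the iteration order of the inputs.
    """
    if not positives:
        raise ValueError("positive protein set is empty")
    if not positives <= background:
        raise ValueError(
            f"positives not contained in background: "
            f"{sorted(positives - background)[:5]} ..."
        )
    n = len(positives)
    N = len(background)

    term_pos: dict[str, int] = {}
    term_bg: dict[str, int] = {}
    for p in background:
        for t in table.terms_of(p):
            term_bg[t] = term_bg.get(t, 0) + 1
            if p in positives:
                term_pos[t] = term_pos.get(t, 0) + 1
    m = len(term_bg)

    rows = []
    for term in sorted(term_bg):
        k, K = term_pos.get(term, 0), term_bg[term]
        p_over, p_under = hypergeometric_test(k, n, K, N)
        p_raw = min(p_over, p_under)
        rows.append(
            {
                "source": table.source,
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "direction": "over" if p_over <= p_under else "under",
                "p_raw": p_raw,
                "p_corrected": min(1.0, p_raw * m),
            }
        )
    df = pd.DataFrame(rows, columns=ENRICH_COLUMNS)
    return df.sort_values(
        ["p_corrected", "p_raw", "term"], kind="mergesort", ignore_index=True
    )


def select_features(
    records: pd.DataFrame, alpha: float = 1e-2, cap: int = 100
) -> pd.DataFrame:
    """Keep significant terms, capped at the most significant ``cap``.

    Records with ``p_corrected < alpha`` are kept; if more than ``cap``
    remain, the ``cap`` with smallest ``p_corrected`` are kept, ties broken
    by ``p_raw`` then term id. An empty selection is legal.
    """
    if records.empty:
        return records.copy()
    sig = records[records["p_corrected"] < alpha]
    sig = sig.sort_values(
        ["p_corrected", "p_raw", "term"], kind="mergesort", ignore_index=True
    )
    return sig.head(cap).copy()


@dataclass
class FeatureSpace:
    """The fixed vector layout a trained classifier commits to.

    The first ``20 * L`` bits one-hot encode the window (position-major,
    alphabet ``ACDEFGHIKLMNPQRSTVWY``) when ``include_seq`` is true; the
    remaining ``len(selected)`` bits flag, in order, whether the site's
    protein carries each selected ``(source, term)`` pair.
    """

    L: int
    selected: list[tuple[str, str]] = field(default_factory=list)
    include_seq: bool = True

    def __post_init__(self) -> None:
        if self.L % 2 == 0:
            raise ValueError("L must be odd")
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate (source, term) pairs in feature space")
        self.selected = [(str(s), str(t)) for s, t in self.selected]

    @property
    def n_functional(self) -> int:
        return len(self.selected)

    @property
    def dimension(self) -> int:
        return (20 * self.L if self.include_seq else 0) + len(self.selected)

    def counts_by_source(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s, _ in self.selected:
            out[s] = out.get(s, 0) + 1
        return out

    def save(self, path) -> None:
        """Serialize to versioned plain text; :meth:`load` is bit-exact."""
        with open(path, "w") as fh:
            fh.write("#lysvote-featurespace\tv1\n")
            fh.write(f"#L\t{self.L}\n")
            fh.write(f"#include_seq\t{int(self.include_seq)}\n")
            fh.write("source\tterm\n")
            for s, t in self.selected:
                fh.write(f"{s}\t{t}\n")

    @classmethod
    def load(cls, path) -> "FeatureSpace":
        with open(path) as fh:
            lines = fh.read().splitlines()
        if not lines or lines[0] != "#lysvote-featurespace\tv1":
            raise ValueError(f"{path} is not a v1 feature-space file")
        meta = {}
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#") and i > 0:
                key, _, val = line[1:].partition("\t")
                meta[key] = val
            elif i > 0:
                body_start = i
                break
        if lines[body_start] != "source\tterm":
            raise ValueError(f"malformed feature-space header in {path}")
        selected = [tuple(line.split("\t", 1)) for line in lines[body_start + 1 :] if line]
        return cls(
            L=int(meta["L"]),
            selected=selected,  # type: ignore[arg-type]
            include_seq=bool(int(meta.get("include_seq", "1"))),
        )


def build_feature_space(
    L: int,
    selections: Mapping[str, pd.DataFrame],
    include_seq: bool = True,
    source_order: tuple[str, ...] = SOURCES,
) -> FeatureSpace:
    """Concatenate per-source selections into one ordered feature space."""
    selected: list[tuple[str, str]] = []
    for src in source_order:
        if src in selections:
            selected.extend((src, t) for t in selections[src]["term"])
    return FeatureSpace(L=L, selected=selected, include_seq=include_seq)
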