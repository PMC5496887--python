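"""Self-contained synthetic fixtures: proteome, substrate sites, annotations,
PPI links.

The generator emulates the statistical structure the prediction method relies
on: substrate proteins of an enzyme preferentially share functional context
(designated "signal" annotation terms and interaction with a hub protein,
standing in for the enzyme itself and its complex partners), while the
peptide sequence around the modified lysine carries at most a weak positional
bias. By default the sequence bias is off, so the discriminative signal is
purely functional.

Everything is reproducible from the seed, and the generator emits exactly the
text formats the rest of the package consumes, plus a ``truth/`` subdirectory
that training code paths never read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import AnnotationTable
from .sequence import STANDARD_AA, write_fasta

#: weak positional preferences applied to positive windows when
#: seq_motif_strength > 0 (offset from the central lysine -> residue)
MOTIF = {-2: "A", -1: "K", 1: "T", 5: "E"}

_FUNC_SOURCES = ("BP", "CC", "MF", "DOMAIN")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a synthetic fixture.

    Defaults describe the standard planted-signal benchmark: 500 proteins of
    which 30 are substrates carrying 1-4 modified lysines each, five signal
    terms carried by 90% of substrates versus 5% of the background, a PPI hub
    wired the same way, and no sequence motif.
    """

    n_proteins: int = 500
    protein_length: tuple[int, int] = (200, 400)
    n_substrate_proteins: int = 30
    sites_per_substrate: tuple[int, int] = (1, 4)
    n_terms_per_source: int = 40
    n_signal_terms: int = 5
    p_signal_in_substrate: float = 0.9
    p_signal_in_background: float = 0.05
    p_background_term: float = 0.05
    seq_motif_strength: float = 0.0
    ppi_hub: bool = True
    n_random_ppi: int = 500
    n_candidates: int = 0
    L: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_substrate_proteins > self.n_proteins:
            raise ValueError("more substrate proteins than proteins")
        if not 0 <= self.p_signal_in_background <= self.p_signal_in_substrate <= 1:
            raise ValueError(
                "planted-signal fixtures require "
                "0 <= p_signal_in_background <= p_signal_in_substrate <= 1"
            )
        if self.seq_motif_strength < 0:
            raise ValueError("seq_motif_strength must be >= 0")
        if self.L % 2 == 0:
            raise ValueError("L must be odd")

    def null(self) -> "SynthConfig":
        """The no-signal control: same shape, nothing planted."""
        return replace(
            self,
            p_signal_in_substrate=self.p_signal_in_background,
            seq_motif_strength=0.0,
            ppi_hub=False,
        )


@dataclass
class SyntheticFixture:
    """In-memory fixture; :meth:`write` emits the on-disk text formats."""

    proteome: dict[str, str]
    positives: pd.DataFrame  # protein_id, position
    tables: dict[str, AnnotationTable]
    ppi_links: pd.DataFrame  # protein_a, protein_b, score
    truth: pd.DataFrame  # protein_id, position
    signal_terms: list[tuple[str, str]]
    hub_id: str | None
    candidates: pd.DataFrame  # protein_id, position (may be empty)
    config: SynthConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def substrate_proteins(self) -> set[str]:
        return set(self.positives["protein_id"])

    def write(self, outdir) -> dict[str, Path]:
        """Write proteome.fasta, positives.tsv, annotations.tsv,
        ppi_links.tsv, candidates.tsv and truth/truth.tsv under ``outdir``."""
        from .annotations import write_annotation_tsv

        d = Path(outdir)
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteome": d / "proteome.fasta",
            "positives": d / "positives.tsv",
            "annotations": d / "annotations.tsv",
            "ppi_links": d / "ppi_links.tsv",
            "candidates": d / "candidates.tsv",
        }
        write_fasta(self.proteome, paths["proteome"])
        self.positives.to_csv(paths["positives"], sep="\t", index=False)
        write_annotation_tsv(self.tables, paths["annotations"])
        self.ppi_links.to_csv(paths["ppi_links"], sep="\t", index=False)
        self.candidates.to_csv(paths["candidates"], sep="\t", index=False)
        truth_dir = d / "truth"
        truth_dir.mkdir(exist_ok=True)
        paths["truth"] = truth_dir / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_protein(rng: np.random.Generator, length: int) -> list[str]:
    return [STANDARD_AA[i] for i in rng.integers(0, 20, size=length)]


def _interior_lysines(seq: list[str], half: int) -> list[int]:
    """0-based indices of K at least ``half`` residues from both termini."""
    return [
        i for i in range(half, len(seq) - half) if seq[i] == "K"
    ]


def generate_fixture(config: SynthConfig) -> SyntheticFixture:
    """Generate a complete fixture from the seed in ``config``.

    Protein sequences are i.i.d. uniform over the 20 standard residues.
    Substrate proteins receive 1-4 modified-lysine sites at interior
    positions (forcing a lysine in when a protein lacks enough); every
    planted site supports a full window at ``config.L``. Substrates carry
    each signal term with ``p_signal_in_substrate``, all other proteins with
    ``p_signal_in_background``; non-signal terms are carried uniformly at
    ``p_background_term``. The PPI hub is a designated non-substrate protein
    linked to substrates at the substrate signal rate (score 900); random
    links at lower scores provide background.
    """
    rng = np.random.default_rng(config.seed)
    half = config.L // 2
    lo, hi = config.protein_length
    ids = [f"P{i:04d}" for i in range(config.n_proteins)]
    seqs: dict[str, list[str]] = {
        pid: _random_protein(rng, int(rng.integers(lo, hi + 1))) for pid in ids
    }

    substrate_ids = sorted(
        ids[i] for i in rng.choice(config.n_proteins,
                                   size=config.n_substrate_proteins,
                                   replace=False)
    )

    # plant modified lysines (forcing K where a protein lacks interior ones)
    s_lo, s_hi = config.sites_per_substrate
    pos_rows: list[tuple[str, int]] = []
    for pid in substrate_ids:
        seq = seqs[pid]
        want = int(rng.integers(s_lo, s_hi + 1))
        sites = _interior_lysines(seq, half)
        guard = 0
        while len(sites) < want:
            i = int(rng.integers(half, len(seq) - half))
            seq[i] = "K"
            sites = _interior_lysines(seq, half)
            guard += 1
            if guard > 10 * want + 100:
                raise ValueError(f"could not place {want} lysines in {pid}")
        chosen = sorted(
            sites[j] for j in rng.choice(len(sites), size=want, replace=False)
        )
        for i in chosen:
            if config.seq_motif_strength > 0:
                centers = set(chosen)
                for off, aa in MOTIF.items():
                    j = i + off
                    if 0 <= j < len(seq) and j not in centers:
                        if rng.random() < min(1.0, config.seq_motif_strength):
                            seq[j] = aa
            pos_rows.append((pid, i + 1))
    # motif planting may overwrite a residue adjacent to another chosen site;
    # centers themselves are protected above
    positives = pd.DataFrame(pos_rows, columns=["protein_id", "position"])

    proteome = {pid: "".join(seq) for pid, seq in seqs.items()}

    # annotation tables with planted signal terms
    substrate_set = set(substrate_ids)
    signal_terms: list[tuple[str, str]] = [
        (_FUNC_SOURCES[i % len(_FUNC_SOURCES)],
         f"{_FUNC_SOURCES[i % len(_FUNC_SOURCES)]}_sig{i}")
        for i in range(config.n_signal_terms)
    ]
    tables: dict[str, AnnotationTable] = {}
    for src in _FUNC_SOURCES:
        mapping: dict[str, set[str]] = {pid: set() for pid in ids}
        terms = [f"{src}_t{j:03d}" for j in range(config.n_terms_per_source)]
        for term in terms:
            carry = rng.random(config.n_proteins) < config.p_background_term
            for pid, c in zip(ids, carry):
                if c:
                    mapping[pid].add(term)
        for s_src, s_term in signal_terms:
            if s_src != src:
                continue
            for pid in ids:
                p = (config.p_signal_in_substrate if pid in substrate_set
                     else config.p_signal_in_background)
                if rng.random() < p:
                    mapping[pid].add(s_term)
        tables[src] = AnnotationTable(
            src, {p: frozenset(t) for p, t in mapping.items() if t}
        )

    # PPI links: hub wiring plus random background edges
    hub_id: str | None = None
    link_rows: list[tuple[str, str, int]] = []
    if config.ppi_hub:
        non_substrates = [pid for pid in ids if pid not in substrate_set]
        hub_id = non_substrates[int(rng.integers(len(non_substrates)))]
        for pid in ids:
            if pid == hub_id:
                continue
            p = (config.p_signal_in_substrate if pid in substrate_set
                 else config.p_signal_in_background)
            if rng.random() < p:
                link_rows.append((hub_id, pid, 900))
    for _ in range(config.n_random_ppi):
        i, j = rng.choice(config.n_proteins, size=2, replace=False)
        link_rows.append((ids[int(i)], ids[int(j)], int(rng.integers(150, 1000))))
    ppi_links = pd.DataFrame(link_rows, columns=["protein_a", "protein_b", "score"])

    # candidate sites for proteome-wide prediction: random full-window lysines
    cand_rows: list[tuple[str, int]] = []
    if config.n_candidates > 0:
        all_sites = [
            (pid, i + 1)
            for pid in ids
            for i in _interior_lysines(list(proteome[pid]), half)
        ]
        take = min(config.n_candidates, len(all_sites))
        for j in rng.choice(len(all_sites), size=take, replace=False):
            cand_rows.append(all_sites[int(j)])
        cand_rows.sort()
    candidates = pd.DataFrame(cand_rows, columns=["protein_id", "position"])

    return SyntheticFixture(
        proteome=proteome,
        positives=positives,
        tables=tables,
        ppi_links=ppi_links,
        truth=positives.copy(),
        signal_terms=signal_terms,
        hub_id=hub_id,
        candidates=candidates,
        config=config,
    )
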