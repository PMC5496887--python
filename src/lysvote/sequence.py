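"""Proteome I/O and lysine-centered peptide windows.

A *site* is a lysine residue identified by ``(protein_id, position)`` with
``position`` 1-based. Classifiers never see the protein directly: each site is
represented by the odd-length peptide window centered on the lysine. Sites
whose full window would run past either protein terminus are dropped (no
padding) unless a pad character is requested explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO

#: the 20 standard residues, alphabetical; also the one-hot alphabet order
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: residues legal in input sequences beyond the standard 20
AMBIGUITY_AA = "XBZUO"

LABELS = ("positive", "negative", "unlabeled")


class ProteinRecord(NamedTuple):
    """A protein sequence with its accession."""

    id: str
    sequence: str


@dataclass(frozen=True)
class SiteWindow:
    """A lysine-centered peptide window.

    Attributes
    ----------
    protein_id : str
        Accession of the parent protein.
    position : int
        1-based index of the central lysine in the protein.
    window : str
        Peptide of odd length ``L`` with ``'K'`` at the center.
    label : str
        One of ``positive``, ``negative``, ``unlabeled``.
    """

    protein_id: str
    position: int
    window: str
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        L = len(self.window)
        if L % 2 == 0:
            raise ValueError(f"window length must be odd, got {L}")
        if self.window[L // 2] != "K":
            raise ValueError(
                f"window center must be 'K': {self.protein_id}:{self.position} "
                f"has {self.window[L // 2]!r}"
            )
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def site(self) -> tuple[str, int]:
        return (self.protein_id, self.position)


@dataclass
class SiteSet:
    """An ordered collection of same-length :class:`SiteWindow` objects.

    ``dropped`` records ``(protein_id, position)`` pairs of sites whose full
    window did not fit inside the protein and were therefore excluded.
    """

    windows: list[SiteWindow]
    L: int
    dropped: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.L % 2 == 0:
            raise ValueError("L must be odd")
        seen: set[tuple[str, int]] = set()
        for w in self.windows:
            if len(w.window) != self.L:
                raise ValueError(
                    f"window length {len(w.window)} != L={self.L} at {w.site}"
                )
            if w.site in seen:
                raise ValueError(f"duplicate site {w.site}")
            seen.add(w.site)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[SiteWindow]:
        return iter(self.windows)

    def __getitem__(self, i: int) -> SiteWindow:
        return self.windows[i]

    def protein_ids(self) -> set[str]:
        return {w.protein_id for w in self.windows}

    def subset(self, proteins: Iterable[str]) -> "SiteSet":
        keep = set(proteins)
        return SiteSet([w for w in self.windows if w.protein_id in keep], self.L)

    def relabel(self, label: str) -> "SiteSet":
        return SiteSet(
            [SiteWindow(w.protein_id, w.position, w.window, label) for w in self],
            self.L,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": [w.protein_id for w in self],
                "position": [w.position for w in self],
                "window": [w.window for w in self],
                "label": [w.label for w in self],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA into an ordered ``{id: sequence}`` mapping.

    The record id is the description line up to the first whitespace.
    """
    proteome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"empty record id in {path}")
        if rec.id in proteome:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if len(seq) < 1:
            raise ValueError(f"empty sequence for {rec.id!r}")
        proteome[rec.id] = seq
    return proteome


def write_fasta(proteome: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteome.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_site_table(path) -> pd.DataFrame:
    """Read a headered TSV with columns ``protein_id``, ``position`` (1-based).

    Duplicate rows are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = {"protein_id", "position"} - set(df.columns)
    if missing:
        raise ValueError(f"site table {path} missing columns {sorted(missing)}")
    df["position"] = df["position"].astype(int)
    n0 = len(df)
    df = df.drop_duplicates(subset=["protein_id", "position"], ignore_index=True)
    if len(df) < n0:
        warnings.warn(
            f"{n0 - len(df)} duplicate (protein_id, position) rows dropped from {path}"
        )
    return df


def extract_windows(
    proteome: Mapping[str, str],
    sites: pd.DataFrame | Sequence[tuple[str, int]],
    L: int,
    label: str = "positive",
    pad_char: str | None = None,
) -> SiteSet:
    """Extract the length-``L`` window around each listed lysine.

    Parameters
    ----------
    proteome : mapping of accession to sequence.
    sites : DataFrame with ``protein_id``/``position`` columns, or an iterable
        of ``(protein_id, position)`` pairs; positions are 1-based.
    L : odd window length.
    label : label assigned to every extracted window.
    pad_char : if given (e.g. ``"X"``), terminal windows are completed with
        this character instead of being dropped.

    Returns
    -------
    SiteSet
        One window per site that fits; dropped sites are listed in
        ``SiteSet.dropped`` in input order.

    Raises
    ------
    KeyError
        If any site references an unknown protein (all offenders listed).
    ValueError
        If any site's residue is not lysine.
    """
    if L % 2 == 0:
        raise ValueError(f"L must be odd, got {L}")
    if isinstance(sites, pd.DataFrame):
        pairs = list(zip(sites["protein_id"].astype(str), sites["position"].astype(int)))
    else:
        pairs = [(str(p), int(x)) for p, x in sites]

    unknown = sorted({p for p, _ in pairs if p not in proteome})
    if unknown:
        raise KeyError(f"site table references unknown proteins: {unknown}")

    half = L // 2
    windows: list[SiteWindow] = []
    dropped: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    for pid, pos in pairs:
        if (pid, pos) in seen:
            continue
        seen.add((pid, pos))
        seq = proteome[pid]
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"position {pos} outside protein {pid} (len {len(seq)})")
        if seq[pos - 1] != "K":
            raise ValueError(
                f"site {pid}:{pos} is {seq[pos - 1]!r}, expected 'K'"
            )
        lo, hi = pos - 1 - half, pos - 1 + half + 1
        if lo < 0 or hi > len(seq):
            if pad_char is None:
                dropped.append((pid, pos))
                continue
            left = pad_char * max(0, -lo)
            right = pad_char * max(0, hi - len(seq))
            window = left + seq[max(lo, 0) : min(hi, len(seq))] + right
        else:
            window = seq[lo:hi]
        windows.append(SiteWindow(pid, pos, window, label))
    return SiteSet(windows, L, dropped=dropped)


def build_background(
    proteome: Mapping[str, str],
    excluded_proteins: Iterable[str],
    L: int,
) -> SiteSet:
    """Enumerate every full-window lysine site outside ``excluded_proteins``.

    This is the negative-sampling universe: all lysine-centered sites of the
    proteome after excluding the known substrate proteins. Order is
    deterministic (protein id, then position); windows are ``unlabeled``.
    """
    if L % 2 == 0:
        raise ValueError(f"L must be odd, got {L}")
    excluded = set(excluded_proteins)
    half = L // 2
    windows: list[SiteWindow] = []
    for pid in sorted(set(proteome) - excluded):
        seq = proteome[pid]
        for i, aa in enumerate(seq):
            if aa == "K" and i - half >= 0 and i + half + 1 <= len(seq):
                windows.append(
                    SiteWindow(pid, i + 1, seq[i - half : i + half + 1], "unlabeled")
                )
    if not windows:
        raise ValueError(
            "background is empty: no full-window lysine sites outside the "
            "excluded proteins"
        )
    return SiteSet(windows, L)


def window_identity(a: str, b: str) -> float:
    """Ungapped fraction of identical aligned positions between two windows."""
    if len(a) != len(b):
        raise ValueError("windows must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def filter_redundancy(sites: SiteSet, threshold: float = 0.70) -> SiteSet:
    """Greedy redundancy reduction at a pairwise identity threshold.

    Scanning in input order, a window is kept iff its ungapped identity to
    every previously kept window is <= ``threshold``. With the default 0.70,
    groups of windows sharing more than 70% identity keep only their first
    member.
    """
    kept: list[SiteWindow] = []
    for w in sites:
        if all(window_identity(w.window, k.window) <= threshold for k in kept):
            kept.append(w)
    return SiteSet(kept, sites.L)


def position_frequency(sites: SiteSet) -> pd.DataFrame:
    """Per-position amino-acid frequencies across a window set.

    Returns a DataFrame indexed by offset from the central lysine
    (``-h .. h``) with one column per standard residue. Ambiguity codes are
    excluded from both numerator and denominator at their position, so each
    row sums to 1 when no ambiguity codes are present and to <= 1 otherwise.
    The center row is 1.0 for K by construction.
    """
    if len(sites) == 0:
        raise ValueError("cannot compute frequencies of an empty site set")
    half = sites.L // 2
    offsets = range(-half, half + 1)
    rows = []
    for j, off in enumerate(offsets):
        column = [w.window[j] for w in sites]
        denom = sum(aa in STANDARD_AA for aa in column)
        counts = {aa: 0 for aa in STANDARD_AA}
        for aa in column:
            if aa in STANDARD_AA:
                counts[aa] += 1
        rows.append(
            {aa: (counts[aa] / denom if denom else 0.0) for aa in STANDARD_AA}
        )
    return pd.DataFrame(rows, index=pd.Index(offsets, name="offset"))
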