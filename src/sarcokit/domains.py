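"""PEVK sliding-window scanning and curation of domain-annotation tables.

Titin-family proteins carry intrinsically disordered spring segments rich
in proline, glutamate, valine and lysine (the PEVK region). Because these
segments are compositionally rather than motif-defined, they are located
by sliding a fixed-length window (default 250 residues) along the protein
and calling every window whose P/E/V/K proportion is strictly above a
threshold (default 40%); qualifying windows are merged into PEVK domain
intervals. Structured domains (Ig, Fn3, kinase, Z-repeats) come from an
external annotation table, curated down to those classes of interest.

Coordinates are 1-based inclusive residue positions throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "PevkProfile",
    "DomainInterval",
    "pevk_fraction_profile",
    "call_pevk_domains",
    "filter_annotation_table",
    "architecture_summary",
    "contour_length",
    "DEFAULT_WINDOW",
    "DEFAULT_THRESHOLD",
    "DEFAULT_KEEP_CLASSES",
]

DEFAULT_WINDOW = 250
DEFAULT_THRESHOLD = 0.40
DEFAULT_KEEP_CLASSES = ("Ig", "Fn3", "Kinase", "Z-repeat")

NM_PER_RESIDUE = 0.35  # contour length of a fully extended polypeptide

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence.upper()) - _STANDARD - {"X"}
        if bad:
            raise ValueError(f"non-amino-acid characters: {sorted(bad)}")


@dataclass(frozen=True)
class PevkProfile:
    """P/E/V/K proportion for every window start position."""

    window_length: int
    positions: np.ndarray  # 1-based window starts
    fractions: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True, order=True)
class DomainInterval:
    start: int
    end: int
    domain_class: str = "PEVK"
    source: str = "scan"  # scan | curated

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad interval ({self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def contour_length(n_residues: int, nm_per_residue: float = NM_PER_RESIDUE) -> float:
    """Contour length in nm of a fully extended chain of n residues.

    E.g. the 1700-residue PEVK segment encoded by one large spring exon
    extends to 1700 x 0.35 = 595 nm.
    """
    return n_residues * nm_per_residue


def pevk_fraction_profile(
    record: ProteinRecord, window_length: int = DEFAULT_WINDOW
) -> PevkProfile:
    """Proportion of P, E, V, K residues in every window of the sequence.

    Case-insensitive; 'X' and other non-P/E/V/K residues count in the
    denominator only. Sequences shorter than the window yield an empty
    profile with a warning.
    """
    seq = record.sequence.upper()
    n = len(seq)
    if n < window_length:
        warnings.warn(
            f"sequence {record.id!r} shorter than window "
            f"({n} < {window_length}): no PEVK calls possible",
            stacklevel=2,
        )
        return PevkProfile(window_length, np.array([], dtype=int), np.array([]))
    is_pevk = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mask = np.isin(is_pevk, np.frombuffer(b"PEVK", dtype=np.uint8))
    csum = np.concatenate([[0], np.cumsum(mask)])
    counts = csum[window_length:] - csum[:-window_length]
    starts = np.arange(1, n - window_length + 2)
    return PevkProfile(window_length, starts, counts / window_length)


def call_pevk_domains(
    profile: PevkProfile, threshold: float = DEFAULT_THRESHOLD
) -> list[DomainInterval]:
    """Merge all windows with P/E/V/K fraction strictly above threshold.

    A window starting at s covers residues s..s+window-1; overlapping or
    adjacent qualifying windows are merged into single intervals. The
    threshold comparison is strict ("more than 40%"): a window at exactly
    the threshold is not called.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    w = profile.window_length
    hits = profile.positions[profile.fractions > threshold]
    intervals: list[DomainInterval] = []
    for s in hits:
        start, end = int(s), int(s) + w - 1
        if intervals and start <= intervals[-1].end + 1:
            last = intervals[-1]
            intervals[-1] = DomainInterval(last.start, max(last.end, end),
                                           "PEVK", "scan")
        else:
            intervals.append(DomainInterval(start, end, "PEVK", "scan"))
    return intervals


def _normalize_class(label: str) -> str:
    key = label.strip().lower().replace("_", "-")
    aliases = {
        "ig": "Ig", "immunoglobulin": "Ig", "ig-like": "Ig",
        "fn3": "Fn3", "fibronectin-type-iii": "Fn3", "fibronectin-iii": "Fn3",
        "kinase": "Kinase", "protein-kinase": "Kinase",
        "z-repeat": "Z-repeat", "zrepeat": "Z-repeat", "z-rep": "Z-repeat",
        "pevk": "PEVK",
    }
    return aliases.get(key, label.strip())


def filter_annotation_table(
    table: pd.DataFrame | Iterable[Sequence],
    keep_classes: Sequence[str] = DEFAULT_KEEP_CLASSES,
) -> list[DomainInterval]:
    """Curate an external domain-annotation table.

    Rows carry (protein_id, class, start, end); only rows whose class maps
    to ``keep_classes`` survive. Malformed rows are skipped with a logged
    warning. Output is sorted by start position.
    """
    if isinstance(table, pd.DataFrame):
        rows = table[["protein_id", "class", "start", "end"]].itertuples(
            index=False, name=None
        )
    else:
        rows = table
    keep = {_normalize_class(c) for c in keep_classes}
    out: list[DomainInterval] = []
    for i, row in enumerate(rows):
        try:
            _pid, cls, start, end = row
            cls = _normalize_class(str(cls))
            if cls not in keep:
                continue
            out.append(DomainInterval(int(start), int(end), cls, "curated"))
        except (ValueError, TypeError) as exc:
            logger.warning("skipping malformed annotation row %d (%r): %s",
                           i, row, exc)
    return sorted(out, key=lambda d: (d.start, d.end))


def architecture_summary(
    record: ProteinRecord, intervals: Sequence[DomainInterval]
) -> pd.DataFrame:
    """To-scale per-domain table for plotting a protein architecture.

    Columns: domain_class, start, end, length, source, fraction_of_protein.
    Total residue coverage (union of intervals) is attached as
    ``df.attrs['coverage_fraction']``.
    """
    n = len(record.sequence)
    for iv in intervals:
        if iv.end > n:
            raise ValueError(
                f"interval ({iv.start},{iv.end}) exceeds sequence length {n}"
            )
    ivs = sorted(intervals, key=lambda d: (d.start, d.end))
    df = pd.DataFrame(
        {
            "domain_class": [d.domain_class for d in ivs],
            "start": [d.start for d in ivs],
            "end": [d.end for d in ivs],
            "length": [d.length for d in ivs],
            "source": [d.source for d in ivs],
        }
    )
    df["fraction_of_protein"] = df["length"] / n if len(df) else []
    covered = 0
    prev_end = 0
    for d in ivs:
        lo = max(d.start, prev_end + 1)
        if d.end >= lo:
            covered += d.end - lo + 1
            prev_end = max(prev_end, d.end)
    df.attrs["coverage_fraction"] = covered / n
    df.attrs["protein_id"] = record.id
    df.attrs["protein_length"] = n
    return df
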