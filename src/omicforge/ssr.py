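"""MISA-style microsatellite (SSR) detection and summary tables.

A simple sequence repeat is a tandem run of a primitive 1-6 bp motif.  The
scanner reports every maximal run meeting its class-specific minimum repeat
count, selected greedily left to right so that reported intervals on one
sequence never overlap.  Neighbouring repeats separated by at most a fixed
interruption distance are grouped as compound SSRs.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

from ._utils import percent

__all__ = [
    "DEFAULT_MIN_REPEATS",
    "SSRParams",
    "SSRRecord",
    "SSRSummary",
    "find_ssrs",
    "mark_compound",
    "ssr_summary",
    "canonical_motif",
]

#: Minimum tandem repeat count per motif length (MISA defaults).
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

_CLASS_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclasses.dataclass(frozen=True)
class SSRParams:
    """Detection thresholds: minimum repeats per motif length and the maximum
    interruption (bp) between members of a compound SSR."""

    min_repeats: Mapping[int, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    max_interrupt_bp: int = 100

    def __post_init__(self) -> None:
        if set(self.min_repeats) != set(range(1, 7)):
            raise ValueError("min_repeats must define motif lengths 1..6 exactly")
        if any(v < 2 for v in self.min_repeats.values()):
            raise ValueError("minimum repeat counts must be >= 2")


@dataclasses.dataclass(frozen=True)
class SSRRecord:
    """One detected microsatellite; coordinates are 1-based inclusive."""

    seq_id: str
    motif: str
    repeat_count: int
    start_bp: int
    end_bp: int
    compound_id: str | None = None

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    @property
    def canonical(self) -> str:
        return canonical_motif(self.motif)


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal rotation of a motif, for aggregation."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_primitive(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def _maximal_runs(sequence: str, params: SSRParams) -> list[tuple[int, int, str, int]]:
    """All left-maximal qualifying tandem runs as (start, end_excl, motif, count)."""
    n = len(sequence)
    runs: list[tuple[int, int, str, int]] = []
    for m in range(1, 7):
        min_rep = params.min_repeats[m]
        i = 0
        while i + m * min_rep <= n:
            motif = sequence[i : i + m]
            if "N" in motif or not _is_primitive(motif):
                i += 1
                continue
            if i >= m and sequence[i - m : i] == motif:
                i += 1  # not left-maximal: the run was seen at an earlier start
                continue
            count = 1
            j = i + m
            while sequence[j : j + m] == motif:
                count += 1
                j += m
            if count >= min_rep:
                runs.append((i, i + m * count, motif, count))
                i = i + m * count
            else:
                i += 1
    return runs


def find_ssrs(seq_id: str, sequence: str, params: SSRParams | None = None) -> list[SSRRecord]:
    """Detect microsatellites in one sequence.

    The sequence may contain ``N`` (which breaks runs).  Candidate runs are
    maximal exact tandem repeats of primitive motifs; when candidates of
    different motif lengths overlap, the leftmost-starting run wins (shorter
    motif first on a tie), so the reported intervals never overlap.  Partial
    trailing motif copies do not count toward ``repeat_count``.
    """
    params = params or SSRParams()
    seq = sequence.upper()
    if not set(seq) <= set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"invalid characters in sequence {seq_id!r}: {bad}")
    candidates = sorted(_maximal_runs(seq, params), key=lambda r: (r[0], len(r[2]), r[1]))
    records: list[SSRRecord] = []
    last_end = 0  # exclusive
    for start, end, motif, count in candidates:
        if start < last_end:
            continue
        records.append(
            SSRRecord(
                seq_id=seq_id,
                motif=motif,
                repeat_count=count,
                start_bp=start + 1,
                end_bp=end,
            )
        )
        last_end = end
    return records


def mark_compound(
    records: Sequence[SSRRecord], max_interrupt_bp: int = 100
) -> list[SSRRecord]:
    """Group neighbouring SSRs on one sequence into compound SSRs.

    Consecutive records whose gap (bases strictly between them) is at most
    ``max_interrupt_bp`` share a compound id of the form ``<seq_id>:c<k>``;
    records in singleton groups keep ``compound_id=None``.  Input should be
    sorted by (seq_id, start); unsorted input is sorted internally with a
    warning.
    """
    recs = list(records)
    seen: set[str] = set()
    ordered = True
    prev_seq: str | None = None
    for r in recs:
        if r.seq_id != prev_seq:
            if r.seq_id in seen:  # sequence block not contiguous
                ordered = False
                break
            seen.add(r.seq_id)
            prev_seq = r.seq_id
            prev_start = r.start_bp
        elif r.start_bp < prev_start:
            ordered = False
            break
        else:
            prev_start = r.start_bp
    if not ordered:
        warnings.warn("SSR records were not sorted; sorting internally", stacklevel=2)
        recs.sort(key=lambda r: (r.seq_id, r.start_bp))
    out: list[SSRRecord] = []
    group: list[SSRRecord] = []
    counters: dict[str, int] = {}

    def flush(group: list[SSRRecord]) -> None:
        if not group:
            return
        if len(group) == 1:
            out.append(group[0])
            return
        seq_id = group[0].seq_id
        counters[seq_id] = counters.get(seq_id, 0) + 1
        cid = f"{seq_id}:c{counters[seq_id]}"
        out.extend(dataclasses.replace(r, compound_id=cid) for r in group)

    for rec in recs:
        if group and rec.seq_id == group[-1].seq_id and (
            rec.start_bp - group[-1].end_bp - 1 <= max_interrupt_bp
        ):
            group.append(rec)
        else:
            flush(group)
            group = [rec]
    flush(group)
    return out


@dataclasses.dataclass(frozen=True)
class SSRSummary:
    n_sequences_examined: int
    total_bp_examined: int
    total_ssrs: int
    n_sequences_with_ssr: int
    n_sequences_with_more_than_one: int
    n_compound: int
    class_counts: dict[str, int]
    class_percentages: dict[str, float]


def ssr_summary(
    records: Iterable[SSRRecord], n_sequences: int, total_bp: int
) -> SSRSummary:
    """Roll detected SSRs up into the standard two-block summary table:
    whole-scan counts plus the distribution over repeat-type classes."""
    recs = list(records)
    per_seq: dict[str, int] = {}
    class_counts = {name: 0 for name in _CLASS_NAMES.values()}
    n_compound = 0
    for r in recs:
        per_seq[r.seq_id] = per_seq.get(r.seq_id, 0) + 1
        class_counts[_CLASS_NAMES[r.motif_length]] += 1
        if r.compound_id is not None:
            n_compound += 1
    total = len(recs)
    class_pct = {
        name: (percent(count, total, 1) if total else 0.0)
        for name, count in class_counts.items()
    }
    return SSRSummary(
        n_sequences_examined=n_sequences,
        total_bp_examined=total_bp,
        total_ssrs=total,
        n_sequences_with_ssr=len(per_seq),
        n_sequences_with_more_than_one=sum(1 for v in per_seq.values() if v > 1),
        n_compound=n_compound,
        class_counts=class_counts,
        class_percentages=class_pct,
    )
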