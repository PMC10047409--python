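"""Raw small-RNA read cleaning, length distribution and miRNA quantification.

The cleaning cascade mirrors the standard small-RNA preprocessing filter
list: adapter dimers, low-quality reads, N-containing reads, short inserts
(< 18 nt) and contaminants (decoy database hits). Filters are applied in
that fixed order so each read is counted in exactly one removal category and
the accounting identity n_raw = n_valid + sum(removals) holds exactly.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from ._seq import as_dna

log = logging.getLogger(__name__)


@dataclass
class ReadFilterStats:
    n_raw: int = 0
    n_adapter_dimer: int = 0
    n_low_quality: int = 0
    n_with_n: int = 0
    n_short: int = 0
    n_contaminant: int = 0
    n_valid: int = 0

    @property
    def valid_rate(self) -> float:
        return self.n_valid / self.n_raw if self.n_raw else 0.0

    def validate(self) -> None:
        removed = (
            self.n_adapter_dimer
            + self.n_low_quality
            + self.n_with_n
            + self.n_short
            + self.n_contaminant
        )
        if self.n_raw != self.n_valid + removed:
            raise ValueError("read accounting violated: raw != valid + removed")


@dataclass
class CollapsedReads:
    """Unique insert sequence -> read count for one sample."""

    counts: Counter = field(default_factory=Counter)
    sample: str = ""

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())


def find_insert_end(seq: str, adapter: str, min_overlap: int = 6):
    """3' adapter position by longest prefix-of-adapter match at the read end.

    Returns the insert length, or None when no >= ``min_overlap`` exact match
    exists (the read is then kept untrimmed).
    """
    n = len(seq)
    for ov in range(min(n, len(adapter)), min_overlap - 1, -1):
        if seq[n - ov :] == adapter[:ov]:
            return n - ov
    return None


def clean_reads(
    fastq,
    adapter: str,
    min_len: int = 18,
    min_mean_q: float = 20.0,
    contaminant_refs=(),
):
    """Clean one FASTQ file/handle; return (CollapsedReads, ReadFilterStats).

    Filter order is fixed: adapter dimer -> low quality -> N-containing ->
    short -> contaminant; survivors are collapsed to unique sequences.
    Contaminants are flagged by exact or substring match against the decoy
    sequences.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    decoys = [as_dna(d[1] if isinstance(d, tuple) else d) for d in contaminant_refs]
    stats = ReadFilterStats()
    collapsed = CollapsedReads(sample=getattr(fastq, "name", str(fastq)))
    n_untrimmed = 0

    handle = str(fastq) if isinstance(fastq, (str, Path)) else fastq
    records = SeqIO.parse(handle, "fastq")
    index = 0
    while True:
        try:
            rec = next(records)
        except StopIteration:
            break
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from exc
        index += 1
        stats.n_raw += 1
        seq = str(rec.seq).upper()
        quals = rec.letter_annotations["phred_quality"]
        end = find_insert_end(seq, adapter)
        if end is None:
            n_untrimmed += 1
            end = len(seq)
        insert = seq[:end]
        insert_quals = quals[:end]
        if len(insert) == 0:
            stats.n_adapter_dimer += 1
        elif sum(insert_quals) / len(insert_quals) < min_mean_q:
            stats.n_low_quality += 1
        elif "N" in insert:
            stats.n_with_n += 1
        elif len(insert) < min_len:
            stats.n_short += 1
        elif any(insert == d or insert in d for d in decoys):
            stats.n_contaminant += 1
        else:
            stats.n_valid += 1
            collapsed.counts[insert] += 1

    if stats.n_raw and n_untrimmed / stats.n_raw > 0.9:
        log.warning(
            "adapter not found in %.0f%% of reads; wrong adapter sequence?",
            100.0 * n_untrimmed / stats.n_raw,
        )
    stats.validate()
    return collapsed, stats


def length_distribution(reads: CollapsedReads) -> dict:
    """Count-weighted fraction of clean reads per insert length."""
    if not reads.counts:
        raise ValueError("no clean reads")
    total = reads.n_reads
    dist = Counter()
    for seq, c in reads.counts.items():
        dist[len(seq)] += c
    return {length: dist[length] / total for length in sorted(dist)}


@dataclass
class MirnaCounts:
    counts: dict
    unassigned: int
    collisions: int = 0

    @property
    def assigned(self) -> int:
        return sum(self.counts.values())


def quantify_mirnas(reads: CollapsedReads, refs, allow_3p_trim: int = 2) -> MirnaCounts:
    """Assign collapsed reads to mature miRNAs by exact match up to 3' length
    variation.

    A read matches a mature sequence if it equals it, is the mature trimmed
    at the 3' end by <= ``allow_3p_trim`` nt, or extends it at the 3' end by
    <= ``allow_3p_trim`` nt (any bases). No internal mismatches. When several
    references match, the smallest length difference wins, ties broken by
    lexicographically first name; collisions are tallied and logged.
    """
    entries = list(refs.items()) if isinstance(refs, dict) else list(refs)
    if not entries:
        raise ValueError("empty miRNA reference set")
    names = [n for n, _ in entries]
    if len(names) != len(set(names)):
        raise ValueError("reference names must be unique")
    matures = {name: as_dna(seq) for name, seq in entries}

    # prefix -> [(name, trim)] covers exact (trim 0) and 3'-trimmed reads
    prefix_index: dict = {}
    full_index: dict = {}
    for name, seq in matures.items():
        full_index.setdefault(seq, []).append(name)
        for d in range(0, allow_3p_trim + 1):
            if len(seq) - d < 1:
                break
            prefix_index.setdefault(seq[: len(seq) - d], []).append((name, d))

    counts: Counter = Counter()
    unassigned = 0
    collisions = 0
    for read, c in reads.counts.items():
        candidates = list(prefix_index.get(read, ()))
        for d in range(1, allow_3p_trim + 1):  # read extends the mature 3' end
            if len(read) - d < 1:
                break
            for name in full_index.get(read[: len(read) - d], ()):
                candidates.append((name, d))
        if not candidates:
            unassigned += c
            continue
        if len(candidates) > 1:
            collisions += 1
            log.debug("read %s matches %d references", read, len(candidates))
        name, _ = min(candidates, key=lambda nd: (nd[1], nd[0]))
        counts[name] += c
    result = MirnaCounts(dict(counts), unassigned, collisions)
    if result.assigned + result.unassigned != reads.n_reads:
        raise AssertionError("quantification accounting violated")
    return result
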