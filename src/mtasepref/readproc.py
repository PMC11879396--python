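"""Raw hairpin bisulfite FASTQ -> quality-passed, deduplicated, reconstructed reads.

Processing follows the standard deep-enzymology recipe: trim reads to a fixed
length, drop low-quality reads, remove exact duplicate sequences, then use the
two strands co-located on each hairpin read to reconstruct the original
(pre-conversion) sequence of the variable window and call the methylation
state of every top-strand cytosine.

Reconstruction truth table (u = top-strand base, l = bottom-strand base
reoriented into top orientation):

    (A,A) -> A            (T,T) -> T
    (T,C) -> C, top C unmethylated     (C,C) -> C, top C methylated
    (G,A) -> G, bottom C unmethylated  (G,G) -> G, bottom C methylated

Any other pair is a strand mismatch and the read is discarded.  Downstream
analyses use only top-strand methylation calls; bottom-strand calls are
recorded but not exported.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

from Bio import SeqIO

from .design import SubstrateDesign
from .dna import reverse_complement

DEFAULT_TRIM_LENGTH = 128
DEFAULT_MIN_QUALITY = 20.0

#: (top base, reoriented bottom base) -> (original base, top C call, bottom C call)
PAIR_TABLE: dict[tuple[str, str], tuple[str, bool | None, bool | None]] = {
    ("A", "A"): ("A", None, None),
    ("T", "T"): ("T", None, None),
    ("T", "C"): ("C", False, None),
    ("C", "C"): ("C", True, None),
    ("G", "A"): ("G", None, False),
    ("G", "G"): ("G", None, True),
}


@dataclass
class RawRead:
    """One FASTQ read: sequence (may contain N) plus per-base Phred scores."""

    id: str
    sequence: str
    quality: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence and quality lengths differ")

    @property
    def mean_quality(self) -> float:
        return sum(self.quality) / len(self.quality) if self.quality else 0.0


@dataclass
class ProcessedRead:
    """A reconstructed read over the variable window.

    ``original_sequence`` is the inferred pre-conversion top-strand window;
    ``motif_variant`` the bases at the analysis frame around the target C;
    ``other_c_calls`` maps window offsets of non-target top-strand Cs to their
    methylation calls.  Bottom-strand calls are kept for QC only.
    """

    read_id: str
    original_sequence: str
    motif_variant: str
    target_methylated: bool
    other_c_calls: dict[int, bool] = field(default_factory=dict)
    bottom_c_calls: dict[int, bool] = field(default_factory=dict)


@dataclass
class Rejection:
    read_id: str
    reason: str


@dataclass
class QCStats:
    """Read counts per processing stage (conserved ledger)."""

    n_input: int = 0
    n_after_trim: int = 0
    n_quality_fail: int = 0
    n_duplicates: int = 0
    rejections: Counter = field(default_factory=Counter)
    n_accepted: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_input": self.n_input,
                    "n_after_trim": self.n_after_trim,
                    "n_quality_fail": self.n_quality_fail,
                    "n_duplicates": self.n_duplicates,
                    "rejections": dict(self.rejections),
                    "n_accepted": self.n_accepted,
                },
                fh,
                indent=2,
            )


def read_fastq(path) -> list[RawRead]:
    return [
        RawRead(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            quality=list(rec.letter_annotations["phred_quality"]),
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def trim_reads(reads: list[RawRead], length: int = DEFAULT_TRIM_LENGTH) -> list[RawRead]:
    """Truncate every read to its first ``length`` bases; shorter reads pass."""
    return [
        RawRead(r.id, r.sequence[:length], r.quality[:length]) for r in reads
    ]


def quality_filter(
    reads: list[RawRead],
    min_q: float = DEFAULT_MIN_QUALITY,
    per_base: bool = False,
) -> tuple[list[RawRead], int]:
    """Drop reads below the quality threshold; returns (kept, n_removed).

    Default semantics: mean Phred score over the read >= ``min_q``.  With
    ``per_base=True`` every single base must reach ``min_q``.
    """
    if min_q < 0:
        raise ValueError("min_q must be nonnegative")
    if per_base:
        kept = [r for r in reads if r.quality and min(r.quality) >= min_q]
    else:
        kept = [r for r in reads if r.mean_quality >= min_q]
    return kept, len(reads) - len(kept)


def deduplicate(reads: list[RawRead]) -> tuple[list[RawRead], int]:
    """Keep the first occurrence of each distinct sequence string."""
    seen: set[str] = set()
    kept = []
    for r in reads:
        if r.sequence not in seen:
            seen.add(r.sequence)
            kept.append(r)
    return kept, len(reads) - len(kept)


def _anchor_mismatches(observed: str, template: str, ambiguous_from: str) -> int:
    """Mismatches against a constant region, bisulfite-aware: a template base
    ``ambiguous_from`` ('C' on the top/loop strand, read either C or T) counts
    as matching both possible readouts."""
    mm = 0
    for o, t in zip(observed, template):
        if t == ambiguous_from:
            if o not in (ambiguous_from, "T"):
                mm += 1
        elif o != t:
            mm += 1
    return mm


def reconstruct_and_call(
    read: RawRead,
    design: SubstrateDesign,
    max_anchor_mismatch: int = 1,
    anchor_length: int = 12,
) -> ProcessedRead | Rejection:
    """Reconstruct the original variable window from both strands of a hairpin
    read and call methylation at every cytosine.

    The constant left arm, stem-loop and 3' stub anchor the fixed layout (no
    indels are modelled); each is verified with at most
    ``max_anchor_mismatch`` bisulfite-aware mismatches.  Reads not covering
    the full hairpin span are rejected (``truncated``); ambiguous (N) bases or
    strand-inconsistent pairs at variable positions reject the read.
    """
    span = design.read_span
    if len(read.sequence) < span:
        return Rejection(read.id, "truncated")
    seq = read.sequence
    top_span, loop_len = design.top_span, len(design.stem_loop)
    ws, wl = design.window_start, design.window_len

    # verify anchors; all constant regions are read through bisulfite, so
    # template Cs may appear as T
    left = design.left_arm[:anchor_length]
    if _anchor_mismatches(seq[: len(left)], left, "C") > max_anchor_mismatch:
        return Rejection(read.id, "anchor_left")
    loop = design.stem_loop[:anchor_length]
    if _anchor_mismatches(seq[top_span : top_span + len(loop)], loop, "C") > max_anchor_mismatch:
        return Rejection(read.id, "anchor_loop")
    stub = design.right_arm[: design.right_keep]
    if stub and _anchor_mismatches(
        seq[ws + wl : ws + wl + len(stub)], stub, "C"
    ) > max_anchor_mismatch:
        return Rejection(read.id, "anchor_right")

    top = seq[ws : ws + wl]
    bottom_start = top_span + loop_len
    # bottom-strand position pairing with top position j is top_span-1-(ws+j)
    bottom_window = seq[
        bottom_start + (top_span - 1 - (ws + wl - 1)) : bottom_start + (top_span - ws)
    ]
    lower = reverse_complement(bottom_window)  # reoriented into top coordinates

    original = []
    top_calls: dict[int, bool] = {}
    bottom_calls: dict[int, bool] = {}
    for j, (u, l) in enumerate(zip(top, lower)):
        if u == "N" or l == "N":
            return Rejection(read.id, "ambiguous_base")
        entry = PAIR_TABLE.get((u, l))
        if entry is None:
            return Rejection(read.id, "mismatch")
        base, top_call, bottom_call = entry
        original.append(base)
        if top_call is not None:
            top_calls[j] = top_call
        if bottom_call is not None:
            bottom_calls[j] = bottom_call
    original_seq = "".join(original)

    t_off = design.target_offset
    if t_off not in top_calls:
        # target position did not reconstruct to a C
        return Rejection(read.id, "target_not_c")
    return ProcessedRead(
        read_id=read.id,
        original_sequence=original_seq,
        motif_variant="",  # filled by process_reads / analysis frame
        target_methylated=top_calls.pop(t_off),
        other_c_calls=top_calls,
        bottom_c_calls=bottom_calls,
    )


def process_reads(
    reads: list[RawRead],
    design: SubstrateDesign,
    trim_to: int | None = None,
    min_q: float = DEFAULT_MIN_QUALITY,
    per_base_quality: bool = False,
    max_anchor_mismatch: int = 1,
) -> tuple[list[ProcessedRead], QCStats]:
    """Full processing pipeline: trim -> quality filter -> dedup -> reconstruct.

    ``trim_to`` defaults to the design's full hairpin span so that both
    strands of the variable window stay covered; pass 128 to emulate the
    fixed-length trimming used for longer raw sequencer output.
    """
    stats = QCStats(n_input=len(reads))
    if trim_to is None:
        trim_to = design.read_span
    reads = trim_reads(reads, trim_to)
    stats.n_after_trim = len(reads)
    reads, stats.n_quality_fail = quality_filter(reads, min_q, per_base_quality)
    reads, stats.n_duplicates = deduplicate(reads)
    processed: list[ProcessedRead] = []
    for r in reads:
        result = reconstruct_and_call(r, design, max_anchor_mismatch)
        if isinstance(result, Rejection):
            stats.rejections[result.reason] += 1
        else:
            processed.append(result)
    stats.n_accepted = len(processed)
    return processed, stats


def assign_motif_variants(
    processed: list[ProcessedRead],
    design: SubstrateDesign,
    motif: str,
    target_index: int,
) -> list[ProcessedRead]:
    """Fill ``motif_variant`` from the analysis frame around the target C."""
    frame = design.frame_offsets(motif, target_index)
    for p in processed:
        p.motif_variant = "".join(p.original_sequence[i] for i in frame)
    return processed


def write_processed_tsv(processed: list[ProcessedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("# read_id\toriginal_sequence\tmotif_variant\ttarget_methylated\n")
        for p in processed:
            fh.write(
                f"{p.read_id}\t{p.original_sequence}\t{p.motif_variant}\t"
                f"{int(p.target_methylated)}\n"
            )


def read_processed_tsv(path) -> list[ProcessedRead]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            rid, seq, variant, meth = line.rstrip("\n").split("\t")
            out.append(
                ProcessedRead(
                    read_id=rid,
                    original_sequence=seq,
                    motif_variant=variant,
                    target_methylated=bool(int(meth)),
                )
            )
    return out
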