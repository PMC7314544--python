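"""Deep-sequencing editing-outcome quantification.

Pipeline: merge read pairs by ungapped overlap, quality-filter, extract
the randomized molecular barcode (UMI) from read 1, locate and trim the
expected locus flanks by semi-global alignment, collapse PCR duplicates
on the (UMI, sequence) pair, classify each unique amplicon, and report
per-class frequencies with the barcode-limited detection floor.

Classification precedence: a read carrying the termination cassette
(within an edit tolerance) is templated repair even if it has further
errors; otherwise length differences > 1 bp are untemplated indels;
equal-length non-identical reads are SNPs; 1-bp length differences are
reported separately and excluded from both mutation frequencies.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .repair_design import PTS_SEQUENCE
from .seqio import QualifiedRead, reverse_complement

__all__ = [
    "OutcomeClass",
    "MergedAmplicon",
    "UniqueAmplicon",
    "EditingSummary",
    "PipelineResult",
    "merge_pair",
    "quality_filter",
    "extract_umi",
    "match_and_trim_flanks",
    "deduplicate",
    "classify_amplicon",
    "summarize",
    "detection_limit",
    "umi_capacity",
    "approx_find",
    "run_pipeline",
]


class OutcomeClass(enum.Enum):
    EXACT_REF = "exact_ref"
    TEMPLATED_PTS = "templated_pts"
    INDEL = "indel"
    SNP = "snp"
    AMBIGUOUS_1BP = "ambiguous_1bp"
    UNALIGNED = "unaligned"


@dataclass
class MergedAmplicon:
    """A merged read pair, optionally with its UMI split off."""

    seq: str
    quals: tuple[int, ...]
    umi: str | None = None
    pair_id: str = ""

    def __post_init__(self) -> None:
        self.quals = tuple(self.quals)
        if len(self.quals) != len(self.seq):
            raise ValueError("quality track must align to the sequence")


@dataclass(frozen=True)
class UniqueAmplicon:
    """One deduplicated molecule bin."""

    umi: str
    seq: str
    duplicate_count: int

    def __post_init__(self) -> None:
        if self.duplicate_count < 1:
            raise ValueError("duplicate_count must be >= 1")


@dataclass(frozen=True)
class EditingSummary:
    """Per-class unique-molecule counts and percent frequencies."""

    counts: dict[OutcomeClass, int]
    total: int
    templated_pct: float
    indel_pct: float
    snp_pct: float
    limit_of_detection_pct: float

    def to_dict(self) -> dict:
        return {
            "counts": {k.value: v for k, v in self.counts.items()},
            "total_unique": self.total,
            "templated_pct": self.templated_pct,
            "indel_pct": self.indel_pct,
            "snp_pct": self.snp_pct,
            "limit_of_detection_pct": self.limit_of_detection_pct,
        }


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def merge_pair(
    r1: QualifiedRead,
    r2: QualifiedRead,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> MergedAmplicon | None:
    """Merge a read pair by its best ungapped suffix-prefix overlap.

    Read 2 is reverse-complemented first. The overlap with the lowest
    mismatch fraction (ties to the longest) wins, provided it reaches
    ``min_overlap`` and stays within ``max_mismatch_frac``. Disagreements
    resolve toward the higher-quality base; merged quality is the max of
    the two. Returns None (reject) when no acceptable overlap exists.
    """
    seq2 = reverse_complement(r2.seq)
    quals2 = r2.quals[::-1]
    n1, n2 = len(r1.seq), len(seq2)
    max_k = min(n1, n2)
    if max_k < min_overlap:
        return None
    a1, a2 = _as_array(r1.seq), _as_array(seq2)

    def overlap_mismatches(k: int) -> int:
        return int(np.count_nonzero(a1[n1 - k:] != a2[:k]))

    best: tuple[float, int] | None = None  # (mismatch fraction, k)

    # Fast path: anchor the start of the reverse-complemented mate in r1.
    seed_len = min(16, n2)
    seed = seq2[:seed_len]
    pos = r1.seq.find(seed)
    while pos != -1:
        k = n1 - pos
        if min_overlap <= k <= max_k:
            frac = overlap_mismatches(k) / k
            if frac <= max_mismatch_frac and (
                best is None or frac < best[0] or (frac == best[0] and k > best[1])
            ):
                best = (frac, k)
        pos = r1.seq.find(seed, pos + 1)

    if best is None:
        for k in range(max_k, min_overlap - 1, -1):
            frac = overlap_mismatches(k) / k
            if frac <= max_mismatch_frac and (
                best is None or frac < best[0] or (frac == best[0] and k > best[1])
            ):
                best = (frac, k)
    if best is None:
        return None

    k = best[1]
    q1_ov = np.asarray(r1.quals[n1 - k:], dtype=np.int16)
    q2_ov = np.asarray(quals2[:k], dtype=np.int16)
    take_r1 = q1_ov >= q2_ov
    consensus = np.where(take_r1, a1[n1 - k:], a2[:k])
    merged_seq = r1.seq[:n1 - k] + consensus.tobytes().decode("ascii") + seq2[k:]
    merged_quals = (
        r1.quals[:n1 - k]
        + tuple(np.maximum(q1_ov, q2_ov).tolist())
        + quals2[k:]
    )
    return MergedAmplicon(merged_seq, merged_quals, pair_id=r1.name)


def quality_filter(
    amplicon: MergedAmplicon | QualifiedRead,
    min_q: int = 30,
    min_fraction: float = 1.0,
) -> bool:
    """True iff at least ``min_fraction`` of bases have Phred >= ``min_q``."""
    quals = amplicon.quals
    if not quals:
        return False
    good = sum(q >= min_q for q in quals)
    return good / len(quals) >= min_fraction


def extract_umi(
    amplicon: MergedAmplicon, k: int = 6, offset: int = 0
) -> MergedAmplicon | None:
    """Split the k-nt molecular barcode off the merged read.

    The barcode occupies bases [offset, offset+k) of read 1 (default:
    the first k bases). Returns a new amplicon with the barcode removed
    from the analyzed sequence, or None if the read is too short.
    """
    if len(amplicon.seq) <= offset + k:
        return None
    umi = amplicon.seq[offset:offset + k]
    seq = amplicon.seq[:offset] + amplicon.seq[offset + k:]
    quals = amplicon.quals[:offset] + amplicon.quals[offset + k:]
    return MergedAmplicon(seq, quals, umi=umi, pair_id=amplicon.pair_id)


def approx_find(pattern: str, text: str) -> tuple[int, int, int]:
    """Best approximate occurrence of ``pattern`` inside ``text``.

    Semi-global edit-distance alignment (free gaps at both pattern ends
    in the text): returns (edit distance, start, end) of the best-scoring
    substring match, preferring the leftmost end on ties.
    """
    m, n = len(pattern), len(text)
    if m == 0:
        return 0, 0, 0
    col = list(range(m + 1))
    best_dist, best_end = col[m], 0
    for j in range(1, n + 1):
        c = text[j - 1]
        prev_diag = col[0]
        for i in range(1, m + 1):
            sub = prev_diag + (pattern[i - 1] != c)
            ins = col[i] + 1
            dele = col[i - 1] + 1
            prev_diag = col[i]
            col[i] = sub if sub <= ins else ins
            if dele < col[i]:
                col[i] = dele
        if col[m] < best_dist:
            best_dist, best_end = col[m], j
    # Recover the match start by aligning the reversed pattern against
    # the reversed prefix ending at best_end.
    rp, rt = pattern[::-1], text[:best_end][::-1]
    col = list(range(m + 1))
    start = best_end
    best_back = col[m]
    for j in range(1, len(rt) + 1):
        c = rt[j - 1]
        prev_diag = col[0]
        for i in range(1, m + 1):
            sub = prev_diag + (rp[i - 1] != c)
            ins = col[i] + 1
            dele = col[i - 1] + 1
            prev_diag = col[i]
            col[i] = sub if sub <= ins else ins
            if dele < col[i]:
                col[i] = dele
        if col[m] < best_back:
            best_back, start = col[m], best_end - j
    return best_dist, start, best_end


def match_and_trim_flanks(
    amplicon: MergedAmplicon | str,
    flank5: str,
    flank3: str,
    min_overlap: int = 50,
    max_error_rate: float = 0.1,
) -> str | None:
    """Locate both expected locus flanks and trim outside them.

    Each flank must match somewhere in the read with
    ``errors / flank_length <= max_error_rate`` (cutadapt semantics;
    errors = substitutions + indels). Returns the read from the start of
    the 5' flank match through the end of the 3' flank match, or None
    (reject) when either flank is absent.
    """
    seq = amplicon if isinstance(amplicon, str) else amplicon.seq
    if len(flank5) < min_overlap or len(flank3) < min_overlap:
        raise ValueError(f"flanks must be at least {min_overlap} nt")
    max5 = int(max_error_rate * len(flank5))
    max3 = int(max_error_rate * len(flank3))
    if len(seq) < max(len(flank5), len(flank3)):
        return None

    def hamming(a: str, b: str) -> int:
        return sum(x != y for x, y in zip(a, b))

    # Fast paths -- exact anywhere, then substitution-only at the read
    # ends (the common case) -- before the full alignment DP.
    start5 = seq.find(flank5)
    if start5 == -1 and hamming(seq[:len(flank5)], flank5) <= max5:
        start5 = 0
    if start5 == -1:
        dist5, start5, _ = approx_find(flank5, seq)
        if dist5 > max5:
            return None
    end3_exact = seq.rfind(flank3)
    if end3_exact != -1:
        end3 = end3_exact + len(flank3)
    elif hamming(seq[-len(flank3):], flank3) <= max3:
        end3 = len(seq)
    else:
        dist3, _, end3 = approx_find(flank3, seq)
        if dist3 > max3:
            return None
    if end3 <= start5:
        return None
    return seq[start5:end3]


def deduplicate(amplicons: Iterable[MergedAmplicon | tuple[str, str]]
                ) -> list[UniqueAmplicon]:
    """Collapse records sharing an identical (UMI, sequence) pair.

    Accepts MergedAmplicons with UMIs set, or raw (umi, seq) tuples.
    First-seen order is preserved.
    """
    bins: dict[tuple[str, str], int] = {}
    for amp in amplicons:
        if isinstance(amp, tuple):
            umi, seq = amp
        else:
            if amp.umi is None:
                raise ValueError("amplicon has no UMI; run extract_umi first")
            umi, seq = amp.umi, amp.seq
        key = (umi, seq)
        bins[key] = bins.get(key, 0) + 1
    return [UniqueAmplicon(u, s, c) for (u, s), c in bins.items()]


def classify_amplicon(
    seq: str,
    reference: str,
    pts: str = PTS_SEQUENCE,
    pts_max_mismatch: int = 2,
) -> OutcomeClass:
    """Assign one outcome class to a unique amplicon sequence.

    Precedence: templated repair (cassette present within
    ``pts_max_mismatch`` edits) beats everything, so templated reads with
    extra errors stay templated; then indels (>1 bp length difference),
    exact reference match, SNP (equal length, >=1 mismatch), and finally
    the unassigned 1-bp length difference class.
    """
    if not reference or not pts:
        raise ValueError("reference and cassette must be non-empty")
    if pts in seq:
        return OutcomeClass.TEMPLATED_PTS
    if pts_max_mismatch > 0:
        dist, _, _ = approx_find(pts, seq)
        if dist <= pts_max_mismatch:
            return OutcomeClass.TEMPLATED_PTS
    diff = len(seq) - len(reference)
    if abs(diff) > 1:
        return OutcomeClass.INDEL
    if diff == 0:
        return OutcomeClass.EXACT_REF if seq == reference else OutcomeClass.SNP
    return OutcomeClass.AMBIGUOUS_1BP


def umi_capacity(umi_len: int = 6) -> int:
    """Number of distinct DNA barcodes of the given length."""
    if umi_len < 1:
        raise ValueError("umi_len must be >= 1")
    return 4 ** umi_len


def detection_limit(umi_len: int = 6) -> float:
    """Smallest resolvable percent frequency: 100 / 4**umi_len."""
    return 100.0 / umi_capacity(umi_len)


def summarize(
    classified: Sequence[tuple[UniqueAmplicon, OutcomeClass]],
    umi_len: int = 6,
) -> EditingSummary:
    """Per-class percentages over unique molecules, plus the LOD."""
    if not classified:
        raise ValueError("no unique amplicons to summarize")
    counts = {cls: 0 for cls in OutcomeClass}
    for _, cls in classified:
        counts[cls] += 1
    total = len(classified)
    pct = lambda c: 100.0 * counts[c] / total
    return EditingSummary(
        counts=counts,
        total=total,
        templated_pct=pct(OutcomeClass.TEMPLATED_PTS),
        indel_pct=pct(OutcomeClass.INDEL),
        snp_pct=pct(OutcomeClass.SNP),
        limit_of_detection_pct=detection_limit(umi_len),
    )


@dataclass
class PipelineResult:
    """Full accounting of one quantification run."""

    n_pairs: int
    merge_rejected: int
    quality_rejected: int
    umi_rejected: int
    flank_rejected: int
    unique: list[UniqueAmplicon]
    classes: list[OutcomeClass]
    summary: EditingSummary
    dispositions: list[tuple[str, str]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    @property
    def binned_reads(self) -> int:
        return sum(u.duplicate_count for u in self.unique)

    def conservation_holds(self) -> bool:
        """Every input pair accounted for exactly once."""
        return self.n_pairs == (
            self.merge_rejected + self.quality_rejected + self.umi_rejected
            + self.flank_rejected + self.binned_reads
        )

    def write_summary_json(self, path: str | Path) -> None:
        doc = self.summary.to_dict()
        doc.update({
            "n_pairs": self.n_pairs,
            "merge_rejected": self.merge_rejected,
            "quality_rejected": self.quality_rejected,
            "umi_rejected": self.umi_rejected,
            "flank_rejected": self.flank_rejected,
            "binned_reads": self.binned_reads,
            "params": self.params,
        })
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    def write_reads_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as out:
            writer = csv.writer(out, delimiter="\t", lineterminator="\n")
            writer.writerow(["read_id", "disposition"])
            writer.writerows(self.dispositions)


def run_pipeline(
    pairs: Sequence[tuple[QualifiedRead, QualifiedRead]],
    reference: str,
    pts: str = PTS_SEQUENCE,
    umi_len: int = 6,
    umi_offset: int = 0,
    min_q: int = 30,
    min_quality_fraction: float = 1.0,
    min_merge_overlap: int = 20,
    max_merge_mismatch_frac: float = 0.1,
    flank_len: int = 50,
    max_flank_error_rate: float = 0.1,
    pts_max_mismatch: int = 2,
) -> PipelineResult:
    """Run the full quantification pipeline over in-memory read pairs.

    ``reference`` is the expected amplicon (without the UMI); its first
    and last ``flank_len`` bases serve as the 5'/3' expected flanks.
    """
    flank5, flank3 = reference[:flank_len], reference[-flank_len:]
    merge_rej = qual_rej = umi_rej = flank_rej = 0
    kept: list[MergedAmplicon] = []
    dispositions: list[tuple[str, str]] = []
    trim_cache: dict[str, str | None] = {}
    for r1, r2 in pairs:
        merged = merge_pair(r1, r2, min_merge_overlap, max_merge_mismatch_frac)
        if merged is None:
            merge_rej += 1
            dispositions.append((r1.name, "merge_rejected"))
            continue
        if not quality_filter(merged, min_q, min_quality_fraction):
            qual_rej += 1
            dispositions.append((r1.name, "quality_rejected"))
            continue
        with_umi = extract_umi(merged, umi_len, umi_offset)
        if with_umi is None:
            umi_rej += 1
            dispositions.append((r1.name, "umi_rejected"))
            continue
        if with_umi.seq in trim_cache:
            trimmed = trim_cache[with_umi.seq]
        else:
            trimmed = match_and_trim_flanks(
                with_umi, flank5, flank3, flank_len, max_flank_error_rate
            )
            trim_cache[with_umi.seq] = trimmed
        if trimmed is None:
            flank_rej += 1
            dispositions.append((r1.name, "flank_rejected"))
            continue
        kept.append(MergedAmplicon(trimmed, (0,) * len(trimmed),
                                   umi=with_umi.umi, pair_id=r1.name))
        dispositions.append((r1.name, "binned"))

    unique = deduplicate(kept)
    class_cache: dict[str, OutcomeClass] = {}
    classes = []
    for u in unique:
        cls = class_cache.get(u.seq)
        if cls is None:
            cls = classify_amplicon(u.seq, reference, pts, pts_max_mismatch)
            class_cache[u.seq] = cls
        classes.append(cls)
    summary = summarize(list(zip(unique, classes)), umi_len)
    return PipelineResult(
        n_pairs=len(pairs),
        merge_rejected=merge_rej,
        quality_rejected=qual_rej,
        umi_rejected=umi_rej,
        flank_rejected=flank_rej,
        unique=unique,
        classes=classes,
        summary=summary,
        dispositions=dispositions,
        params={
            "umi_len": umi_len, "umi_offset": umi_offset, "min_q": min_q,
            "min_quality_fraction": min_quality_fraction,
            "min_merge_overlap": min_merge_overlap,
            "max_merge_mismatch_frac": max_merge_mismatch_frac,
            "flank_len": flank_len,
            "max_flank_error_rate": max_flank_error_rate,
            "pts_max_mismatch": pts_max_mismatch,
            "pts": pts,
        },
    )
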