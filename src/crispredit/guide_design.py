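"""SpCas9 protospacer scanning, scoring, and filtering.

Scans both strands of a locus for 20-nt protospacers followed by an NGG
PAM, counts mismatches against the 9-nt target-context motif HNNGRSGGH
(protospacer positions 16-20, the PAM, and one base 3' of the PAM, all
read on the protospacer strand), predicts the self-folding free energy
of the targeting sequence, checks genomic contiguity against exon
annotation, and ranks the survivors.

Coordinates are 0-based half-open internally. ``pam_start`` is the
smallest reference coordinate of the PAM triplet regardless of strand;
``cleavage_pos`` is an insertion point in reference coordinates.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .folding import hairpin_mfe
from .seqio import (
    ExonAnnotation,
    NucleotideSequence,
    iupac_match,
    reverse_complement,
)

__all__ = [
    "TARGET_MOTIF",
    "SPACER_LENGTH",
    "DG_THRESHOLD",
    "GuideCandidate",
    "MotifContext",
    "scan_protospacers",
    "motif_mismatch_count",
    "cleavage_site",
    "predict_fold_dg",
    "verify_genomic_contiguity",
    "filter_guides",
    "guides_to_tsv",
]

logger = logging.getLogger(__name__)

TARGET_MOTIF = "HNNGRSGGH"
SPACER_LENGTH = 20
PAM_LENGTH = 3
CONTEXT_LENGTH = SPACER_LENGTH + PAM_LENGTH + 1  # minimum scannable locus
CUT_OFFSET = 3  # blunt cut this many bp upstream of the PAM
DG_THRESHOLD = -1.5  # kcal/mol


@dataclass(frozen=True)
class MotifContext:
    """The 9-nt window scored against HNNGRSGGH.

    Layout: protospacer positions 16-20, then the PAM, then the base
    immediately 3' of the PAM, all on the protospacer strand. SGG is the
    only NGG-compatible 3-mer inside the motif, which fixes the PAM at
    window positions 6-8.
    """

    niner: str

    def __post_init__(self) -> None:
        if len(self.niner) != 9:
            raise ValueError(f"context window must be 9 nt, got {len(self.niner)}")


@dataclass(frozen=True)
class GuideCandidate:
    """A 20-nt SpCas9 protospacer with PAM, coordinates, and scores."""

    protospacer: str
    pam: str
    strand: str
    pam_start: int
    cleavage_pos: int
    motif_mismatches: int
    delta_g: float | None = None
    passes_filter: bool = False
    contig: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if len(self.protospacer) != SPACER_LENGTH:
            raise ValueError("protospacer must be 20 nt")
        if not iupac_match("NGG", self.pam):
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.motif_mismatches <= 9:
            raise ValueError("motif_mismatches must be in [0, 9]")

    @property
    def target_with_pam(self) -> str:
        return self.protospacer + self.pam


def motif_mismatch_count(context: MotifContext | str) -> int:
    """Number of positions of the 9-nt window violating HNNGRSGGH."""
    niner = context.niner if isinstance(context, MotifContext) else context
    if len(niner) != len(TARGET_MOTIF):
        raise ValueError(f"context window must be 9 nt, got {len(niner)}")
    return sum(
        not iupac_match(code, base) for code, base in zip(TARGET_MOTIF, niner)
    )


def cleavage_site(candidate: GuideCandidate) -> int:
    """Reference insertion point of the blunt cut, 3 bp upstream of the PAM.

    On the plus strand the cut sits at ``pam_start - 3``; on the minus
    strand the geometry mirrors to ``pam_start + PAM_LENGTH + 3``.
    """
    if candidate.strand == "+":
        pos = candidate.pam_start - CUT_OFFSET
    else:
        pos = candidate.pam_start + PAM_LENGTH + CUT_OFFSET
    if pos < 0:
        raise ValueError(
            f"cleavage position underflows the reference (pam_start="
            f"{candidate.pam_start}, strand {candidate.strand})"
        )
    return pos


def predict_fold_dg(
    spacer: str, backend: Callable[[str], float] | None = None
) -> float:
    """Predicted folding free energy (kcal/mol) of a targeting sequence.

    Uses the bundled hairpin nearest-neighbor estimator unless an
    external ``backend`` callable is supplied, in which case its value is
    returned verbatim.
    """
    if len(spacer) != SPACER_LENGTH:
        raise ValueError(f"targeting sequence must be {SPACER_LENGTH} nt")
    if backend is not None:
        return float(backend(spacer))
    return hairpin_mfe(spacer)


def scan_protospacers(
    locus: NucleotideSequence | str,
    compute_dg: bool = True,
    backend: Callable[[str], float] | None = None,
) -> list[GuideCandidate]:
    """All NGG-adjacent 20-mers on both strands of a locus.

    Candidates whose 9-nt context window would run off the locus are
    dropped. Motif mismatches are computed for every candidate; folding
    free energies are computed unless ``compute_dg`` is false.
    """
    if isinstance(locus, str):
        locus = NucleotideSequence("locus", locus.upper(), allow_n=True)
    seq = locus.seq
    n = len(seq)
    candidates: list[GuideCandidate] = []
    if n < CONTEXT_LENGTH:
        logger.info(
            "locus %s is %d nt, shorter than the %d nt minimum; no candidates",
            locus.name, n, CONTEXT_LENGTH,
        )
        return candidates

    def _dg(spacer: str) -> float | None:
        return predict_fold_dg(spacer, backend=backend) if compute_dg else None

    # Plus strand: spacer [s, s+20), PAM [s+20, s+23), context base s+23.
    for s in range(0, n - CONTEXT_LENGTH + 1):
        if seq[s + 21] == "G" and seq[s + 22] == "G":
            window = seq[s + 15:s + 24]
            if "N" in seq[s:s + 24]:
                continue
            candidates.append(
                GuideCandidate(
                    protospacer=seq[s:s + 20],
                    pam=seq[s + 20:s + 23],
                    strand="+",
                    pam_start=s + 20,
                    cleavage_pos=s + 20 - CUT_OFFSET,
                    motif_mismatches=motif_mismatch_count(window),
                    delta_g=_dg(seq[s:s + 20]),
                    contig=locus.name,
                )
            )
    # Minus strand: PAM occupies reference [p, p+3) (as CCN), spacer
    # [p+3, p+23), context base p-1.
    for p in range(1, n - CONTEXT_LENGTH + 2):
        if seq[p] == "C" and seq[p + 1] == "C":
            if "N" in seq[p - 1:p + 23]:
                continue
            window = reverse_complement(seq[p - 1:p + 8])
            candidates.append(
                GuideCandidate(
                    protospacer=reverse_complement(seq[p + 3:p + 23]),
                    pam=reverse_complement(seq[p:p + 3]),
                    strand="-",
                    pam_start=p,
                    cleavage_pos=p + PAM_LENGTH + CUT_OFFSET,
                    motif_mismatches=motif_mismatch_count(window),
                    delta_g=_dg(reverse_complement(seq[p + 3:p + 23])),
                    contig=locus.name,
                )
            )
    return candidates


def verify_genomic_contiguity(
    target_with_pam: str,
    genome: NucleotideSequence | str,
    annotation: ExonAnnotation | None = None,
) -> bool:
    """True iff the 23-mer occurs contiguously in the genomic sequence.

    Either orientation counts. With an annotation, the match must also
    lie entirely within a single exon interval; guides assembled across
    exon-exon junctions fail here.
    """
    genome_seq = genome.seq if isinstance(genome, NucleotideSequence) else genome
    hits: list[tuple[int, int]] = []
    for query in (target_with_pam, reverse_complement(target_with_pam)):
        start = genome_seq.find(query)
        while start != -1:
            hits.append((start, start + len(query)))
            start = genome_seq.find(query, start + 1)
    if not hits:
        return False
    if annotation is None:
        return True
    return any(annotation.contains(s, e) for s, e in hits)


def filter_guides(
    candidates: Iterable[GuideCandidate],
    dg_threshold: float = DG_THRESHOLD,
    max_motif_mismatches: int = 0,
) -> list[GuideCandidate]:
    """Apply the folding and motif filters and rank the survivors.

    Keeps candidates with ``delta_g > dg_threshold`` and
    ``motif_mismatches <= max_motif_mismatches``; sorts by mismatches
    ascending, delta_g descending, then reference coordinate ascending.
    """
    kept = []
    for cand in candidates:
        if cand.delta_g is None:
            raise ValueError(f"candidate at {cand.pam_start} has no delta_g")
        if cand.delta_g > dg_threshold and cand.motif_mismatches <= max_motif_mismatches:
            kept.append(replace(cand, passes_filter=True))
    kept.sort(key=lambda c: (c.motif_mismatches, -c.delta_g, c.pam_start))
    return kept


def guides_to_tsv(candidates: Sequence[GuideCandidate], path: str | Path) -> None:
    """Write candidates as TSV with 1-based user-facing coordinates."""
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "guide_id", "contig", "strand", "spacer", "pam", "pam_start",
            "cleavage_pos", "motif_mismatches", "delta_g_kcal_mol",
            "passes_filter",
        ])
        for i, c in enumerate(candidates, start=1):
            writer.writerow([
                f"guide_{i:04d}", c.contig, c.strand, c.protospacer, c.pam,
                c.pam_start + 1, c.cleavage_pos + 1, c.motif_mismatches,
                "" if c.delta_g is None else f"{c.delta_g:.2f}",
                str(c.passes_filter).lower(),
            ])
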