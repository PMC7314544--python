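"""Premature-termination cassette and repair-oligonucleotide design.

The knockout payload is an 18-nt palindromic cassette carrying stop
codons in all three frames on both strands, a polyadenylation signal on
both strands, and a PacI site for restriction genotyping. Knockout
templates copy homology arms from the locus flanking a guide's cleavage
site and insert the cassette at the cut; point-mutation templates swap
an explicit edit span inside a window centered on the cut.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .guide_design import GuideCandidate
from .seqio import (
    NucleotideSequence,
    STRICT_ALPHABET,
    AlphabetError,
    reverse_complement,
    stop_codons_by_frame,
)

__all__ = [
    "PTS_SEQUENCE",
    "POLYA_SIGNAL",
    "PACI_SITE",
    "PTSCassette",
    "PtsValidation",
    "RepairTemplate",
    "make_pts",
    "validate_pts_like",
    "design_knockout_template",
    "design_point_mutation_template",
    "template_panel",
    "templates_to_fasta",
    "templates_to_tsv",
]

PTS_SEQUENCE = "TTTATTTAATTAAATAAA"
POLYA_SIGNAL = "AATAAA"
PACI_SITE = "TTAATTAA"

ORIENTATIONS = ("sense", "antisense", "duplex")


@dataclass(frozen=True)
class PTSCassette:
    """The constant 18-nt premature termination cassette."""

    seq: str = PTS_SEQUENCE

    def __post_init__(self) -> None:
        report = validate_pts_like(self.seq)
        if len(self.seq) != 18 or not report.all_ok:
            raise ValueError(f"{self.seq!r} is not a valid termination cassette")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PtsValidation:
    """Independent structural checks for a candidate termination cassette.

    Positions are 1-based on the forward strand; empty tuples mean no
    occurrence.
    """

    is_palindrome: bool
    stops_all_frames_both_strands: bool
    polya_both_strands: bool
    has_paci_site: bool
    polya_positions: tuple[int, ...]
    paci_positions: tuple[int, ...]

    @property
    def all_ok(self) -> bool:
        return (self.is_palindrome and self.stops_all_frames_both_strands
                and self.polya_both_strands and self.has_paci_site)


def make_pts() -> PTSCassette:
    """The 18-nt knockout cassette; all structural invariants hold."""
    return PTSCassette()


def _find_all(needle: str, haystack: str) -> tuple[int, ...]:
    """1-based start positions of every (possibly overlapping) occurrence."""
    positions = []
    start = haystack.find(needle)
    while start != -1:
        positions.append(start + 1)
        start = haystack.find(needle, start + 1)
    return tuple(positions)


def validate_pts_like(seq: str) -> PtsValidation:
    """Check palindromy, all-frame stops on both strands, poly(A) signals
    on both strands, and the PacI site for any candidate cassette."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - STRICT_ALPHABET
    if bad:
        raise AlphabetError(f"invalid characters {sorted(bad)}")
    rc = reverse_complement(seq)
    if len(seq) >= 3:
        stops = all(stop_codons_by_frame(seq)) and all(stop_codons_by_frame(rc))
    else:
        stops = False
    return PtsValidation(
        is_palindrome=(seq == rc),
        stops_all_frames_both_strands=stops,
        polya_both_strands=(POLYA_SIGNAL in seq and POLYA_SIGNAL in rc),
        has_paci_site=(PACI_SITE in seq),
        polya_positions=_find_all(POLYA_SIGNAL, seq),
        paci_positions=_find_all(PACI_SITE, seq),
    )


@dataclass(frozen=True)
class RepairTemplate:
    """A designed repair oligonucleotide: arms + payload + metadata.

    ``seq`` is the deliverable strand (for duplex designs, the sense
    strand; the second strand is its reverse complement). Modification
    flags are synthesis annotations only and never change the sequence.
    """

    name: str
    seq: str
    payload: str
    left_arm_len: int
    right_arm_len: int
    orientation: str
    insertion_point: int
    source_locus: str = ""
    modifications: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.left_arm_len < 0 or self.right_arm_len < 0:
            raise ValueError("arm lengths must be non-negative")
        if self.left_arm_len == 0 and self.right_arm_len == 0:
            raise ValueError("at least one homology arm must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


def _locus_seq(locus: NucleotideSequence | str) -> tuple[str, str]:
    if isinstance(locus, NucleotideSequence):
        return locus.seq, locus.name
    return locus.upper(), "locus"


def _check_flanks(cut: int, left: int, right: int, n: int) -> None:
    if cut - left < 0:
        raise ValueError(
            f"insufficient 5' flank: need {left} bases upstream of the cut "
            f"at {cut}, short by {left - cut}"
        )
    if cut + right > n:
        raise ValueError(
            f"insufficient 3' flank: need {right} bases downstream of the "
            f"cut at {cut}, short by {cut + right - n}"
        )


def design_knockout_template(
    locus: NucleotideSequence | str,
    guide: GuideCandidate,
    arm_len: int = 50,
    orientation: str = "sense",
    left_arm_len: int | None = None,
    right_arm_len: int | None = None,
    modifications: Sequence[str] = (),
    name: str = "knockout",
) -> RepairTemplate:
    """Homology arms copied from the locus around the cut, cassette between.

    The sense design is ``locus[cut-arm : cut] + PTS + locus[cut : cut+arm]``;
    antisense is its reverse complement; duplex keeps the sense sequence
    and carries the second strand implicitly plus modification metadata.
    """
    seq, locus_name = _locus_seq(locus)
    left = arm_len if left_arm_len is None else left_arm_len
    right = arm_len if right_arm_len is None else right_arm_len
    cut = guide.cleavage_pos
    _check_flanks(cut, left, right, len(seq))
    sense = seq[cut - left:cut] + PTS_SEQUENCE + seq[cut:cut + right]
    template_seq = reverse_complement(sense) if orientation == "antisense" else sense
    return RepairTemplate(
        name=name,
        seq=template_seq,
        payload="PTS",
        left_arm_len=left,
        right_arm_len=right,
        orientation=orientation,
        insertion_point=cut,
        source_locus=locus_name,
        modifications=tuple(modifications),
    )


def design_point_mutation_template(
    locus: NucleotideSequence | str,
    guide: GuideCandidate,
    edit: tuple[int, int, str],
    arm_len: int = 100,
    orientation: str = "sense",
    name: str = "point_edit",
) -> RepairTemplate:
    """Substitution/deletion template centered on the cleavage site.

    ``edit`` is (start, end, replacement) in 0-based half-open reference
    coordinates; the span must lie within the homology window
    ``[cut - arm_len, cut + arm_len)``. Total homology is
    ``2 * arm_len - (end - start)``.
    """
    seq, locus_name = _locus_seq(locus)
    cut = guide.cleavage_pos
    _check_flanks(cut, arm_len, arm_len, len(seq))
    start, end, replacement = edit
    replacement = replacement.upper()
    if replacement and set(replacement) - STRICT_ALPHABET:
        raise AlphabetError(f"invalid replacement bases {replacement!r}")
    win_start, win_end = cut - arm_len, cut + arm_len
    if not (win_start <= start <= end <= win_end):
        raise ValueError(
            f"edit span [{start}, {end}) falls outside the homology window "
            f"[{win_start}, {win_end})"
        )
    sense = seq[win_start:start] + replacement + seq[end:win_end]
    template_seq = reverse_complement(sense) if orientation == "antisense" else sense
    return RepairTemplate(
        name=name,
        seq=template_seq,
        payload=f"edit[{start + 1}-{end}]->{replacement or 'del'}",
        left_arm_len=start - win_start,
        right_arm_len=win_end - end,
        orientation=orientation,
        insertion_point=cut,
        source_locus=locus_name,
    )


def template_panel(
    locus: NucleotideSequence | str,
    guide: GuideCandidate,
    arm_len: int = 50,
    truncated_arm_len: int = 50,
) -> list[RepairTemplate]:
    """The default 7-member panel of knockout repair templates.

    Sense, antisense, three duplex variants (unmodified, 5'-phosphorylated,
    5'-phosphorothioate), and two single-arm sense designs (5'-arm-only
    and 3'-arm-only, ``truncated_arm_len`` long). The roster is a
    configurable default; all members carry the cassette.
    """
    def ko(name: str, **kwargs) -> RepairTemplate:
        return design_knockout_template(locus, guide, arm_len=arm_len,
                                        name=name, **kwargs)

    return [
        ko("S", orientation="sense"),
        ko("A", orientation="antisense"),
        ko("D", orientation="duplex"),
        ko("D-phos", orientation="duplex", modifications=("5'-phosphorylation",)),
        ko("D-thio", orientation="duplex", modifications=("5'-phosphorothioate",)),
        ko("S-5arm", orientation="sense",
           left_arm_len=truncated_arm_len, right_arm_len=0),
        ko("S-3arm", orientation="sense",
           left_arm_len=0, right_arm_len=truncated_arm_len),
    ]


def templates_to_fasta(templates: Sequence[RepairTemplate],
                       path: str | Path) -> None:
    from .seqio import write_fasta

    write_fasta(path, [NucleotideSequence(t.name, t.seq) for t in templates])


def templates_to_tsv(templates: Sequence[RepairTemplate],
                     path: str | Path) -> None:
    """Order-sheet style manifest; insertion points are 1-based."""
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "template_id", "orientation", "payload", "left_arm_len",
            "right_arm_len", "modifications", "insertion_point", "locus",
            "length", "sequence",
        ])
        for t in templates:
            writer.writerow([
                t.name, t.orientation, t.payload, t.left_arm_len,
                t.right_arm_len, ";".join(t.modifications) or "none",
                t.insertion_point + 1, t.source_locus, len(t.seq), t.seq,
            ])
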