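"""Synthetic fixtures: loci with planted guides, simulated paired-end
amplicon runs with molecular barcodes and controlled editing-outcome
frequencies, and synthetic growth series.

Every generator is deterministic given its seed, so pipeline stages can
be tested end-to-end with no external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .amplicon_quant import OutcomeClass
from .growth_models import GrowthSeries, logistic_density
from .repair_design import PTS_SEQUENCE
from .seqio import NucleotideSequence, QualifiedRead, reverse_complement, write_fastq

__all__ = [
    "LocusSim",
    "AmpliconSimSpec",
    "TruthRecord",
    "SimulatedRun",
    "simulate_locus",
    "simulate_amplicon_run",
    "simulate_growth_series",
    "GUIDE_PLANT",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# 24-nt plant: a motif-perfect, unstructured protospacer context.
# spacer (20) + PAM "CGG" + one 3' context base; window = "AACGACGGA",
# zero mismatches against HNNGRSGGH, and the spacer cannot form a helix.
GUIDE_PLANT = "ACAACAACAACAACAAACGA" + "CGG" + "A"


@dataclass(frozen=True)
class LocusSim:
    """A simulated locus and the record of its planted guide."""

    locus: NucleotideSequence
    guide_spacer_start: int | None  # 0-based plus-strand spacer start


def simulate_locus(
    length: int,
    gc: float = 0.5,
    seed: int | None = 0,
    ensure_guide: bool = True,
) -> LocusSim:
    """Random locus at the requested GC content.

    With ``ensure_guide`` a fixed motif-perfect protospacer context (zero
    motif mismatches, unstructured spacer) is planted at a recorded
    position; the plant keeps its own composition regardless of ``gc``.
    """
    if length < 150:
        raise ValueError("locus length must be >= 150")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=probs)
    start = None
    if ensure_guide:
        # keep the plant away from the ends so 50-nt arms always fit
        # around the cut (cut = plant_start + 17)
        margin = 50
        start = int(rng.integers(margin, length - margin - len(GUIDE_PLANT)))
        arr[start:start + len(GUIDE_PLANT)] = np.frombuffer(
            GUIDE_PLANT.encode(), dtype=np.uint8
        )
    seq = arr.tobytes().decode("ascii")
    return LocusSim(NucleotideSequence("sim_locus", seq), start)


@dataclass(frozen=True)
class AmpliconSimSpec:
    """Parameters of one simulated amplicon sequencing run.

    ``templated_frac`` and ``indel_frac`` are molecule-level outcome
    probabilities; ``snp_rate`` is a per-base substitution rate applied
    to otherwise-unedited molecules (true variants, not sequencing
    error). Per-base call errors follow the emitted Phred scores:
    error probability 10**(-Q/10).
    """

    reference: str
    cut_pos: int | None = None
    pts: str = PTS_SEQUENCE
    templated_frac: float = 0.015
    indel_frac: float = 0.001
    snp_rate: float = 0.0
    n_molecules: int = 1000
    dup_mean: float = 3.0
    read_len: int = 300
    umi_len: int = 6
    mean_q: int = 36
    q_jitter: int = 3
    indel_sizes: tuple[int, ...] = tuple(range(2, 11))
    inject_errors: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.reference:
            raise ValueError("reference must be non-empty")
        for name in ("templated_frac", "indel_frac", "snp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.templated_frac + self.indel_frac > 1.0:
            raise ValueError("templated_frac + indel_frac must be <= 1")
        if self.n_molecules < 1 or self.read_len <= self.umi_len:
            raise ValueError("invalid run geometry")
        if self.dup_mean < 1.0:
            raise ValueError("dup_mean must be >= 1")
        if any(s < 2 for s in self.indel_sizes):
            raise ValueError("indel sizes must be >= 2")

    @property
    def cut(self) -> int:
        return len(self.reference) // 2 if self.cut_pos is None else self.cut_pos


@dataclass(frozen=True)
class TruthRecord:
    molecule_id: int
    umi: str
    true_class: OutcomeClass
    n_reads: int


@dataclass
class SimulatedRun:
    """Reads plus ground truth for one simulated run."""

    r1: list[QualifiedRead]
    r2: list[QualifiedRead]
    truth: list[TruthRecord]
    spec: AmpliconSimSpec

    def true_fraction(self, cls: OutcomeClass) -> float:
        return sum(t.true_class is cls for t in self.truth) / len(self.truth)

    def write_fastq_pair(self, path_r1, path_r2) -> None:
        write_fastq(path_r1, self.r1)
        write_fastq(path_r2, self.r2)

    def write_truth_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("molecule_id\tumi\ttrue_class\tn_reads\n")
            for t in self.truth:
                out.write(
                    f"{t.molecule_id}\t{t.umi}\t{t.true_class.value}\t{t.n_reads}\n"
                )

    def write_spec_json(self, path) -> None:
        doc = asdict(self.spec)
        doc["indel_sizes"] = list(doc["indel_sizes"])
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def _mutate_bases(arr: np.ndarray, positions: np.ndarray,
                  rng: np.random.Generator) -> None:
    """Substitute each position with a uniformly drawn different base."""
    for pos in positions:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)


def _make_read(seq: str, spec: AmpliconSimSpec,
               rng: np.random.Generator) -> QualifiedRead:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(arr)
    if spec.q_jitter > 0:
        quals = rng.integers(spec.mean_q - spec.q_jitter,
                             spec.mean_q + spec.q_jitter + 1, size=n)
    else:
        quals = np.full(n, spec.mean_q, dtype=np.int64)
    if spec.inject_errors:
        p_err = np.power(10.0, -quals / 10.0)
        errs = np.nonzero(rng.random(n) < p_err)[0]
        if errs.size:
            _mutate_bases(arr, errs, rng)
    return QualifiedRead("", arr.tobytes().decode("ascii"),
                         tuple(int(q) for q in quals))


def simulate_amplicon_run(spec: AmpliconSimSpec) -> SimulatedRun:
    """Draw molecules, duplicate them as PCR copies, and emit read pairs.

    Each molecule gets one true outcome (templated cassette insertion at
    the cut, an untemplated indel of size >= 2 at the cut, or the exact
    reference, optionally with true SNPs), a uniform random barcode, and
    a geometric number of read pairs sharing that barcode and sequence.
    Base-call errors are injected per read according to the quality
    profile.
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference.upper()
    cut = spec.cut
    if not 0 <= cut <= len(ref):
        raise ValueError("cut position outside the reference")

    templated_seq = ref[:cut] + spec.pts + ref[cut:]
    r1_list: list[QualifiedRead] = []
    r2_list: list[QualifiedRead] = []
    truth: list[TruthRecord] = []

    draws = rng.random(spec.n_molecules)
    p_geom = 1.0 / spec.dup_mean
    for mol_id in range(spec.n_molecules):
        u = draws[mol_id]
        if u < spec.templated_frac:
            mol_seq, cls = templated_seq, OutcomeClass.TEMPLATED_PTS
        elif u < spec.templated_frac + spec.indel_frac:
            size = int(rng.choice(spec.indel_sizes))
            if rng.random() < 0.5 and cut + size <= len(ref):
                mol_seq = ref[:cut] + ref[cut + size:]
            else:
                ins = rng.choice(_BASES, size=size).tobytes().decode("ascii")
                mol_seq = ref[:cut] + ins + ref[cut:]
            cls = OutcomeClass.INDEL
        else:
            mol_seq, cls = ref, OutcomeClass.EXACT_REF
            if spec.snp_rate > 0:
                hits = np.nonzero(rng.random(len(ref)) < spec.snp_rate)[0]
                if hits.size:
                    arr = np.frombuffer(ref.encode(), dtype=np.uint8).copy()
                    _mutate_bases(arr, hits, rng)
                    mol_seq, cls = arr.tobytes().decode("ascii"), OutcomeClass.SNP

        umi = rng.choice(_BASES, size=spec.umi_len).tobytes().decode("ascii")
        n_reads = int(rng.geometric(p_geom)) if spec.dup_mean > 1 else 1
        fwd = (umi + mol_seq)[:spec.read_len]
        rev = reverse_complement(mol_seq)[:spec.read_len]
        for copy in range(n_reads):
            name = f"mol{mol_id}_copy{copy}"
            read1 = _make_read(fwd, spec, rng)
            read2 = _make_read(rev, spec, rng)
            r1_list.append(QualifiedRead(f"{name}/1", read1.seq, read1.quals))
            r2_list.append(QualifiedRead(f"{name}/2", read2.seq, read2.quals))
        truth.append(TruthRecord(mol_id, umi, cls, n_reads))
    return SimulatedRun(r1_list, r2_list, truth, spec)


def simulate_growth_series(
    K: float,
    P0: float,
    T: float,
    noise_cv: float = 0.0,
    times=None,
    replicates: int = 3,
    seed: int | None = 0,
) -> list[GrowthSeries]:
    """Logistic time courses with multiplicative log-normal noise.

    Defaults mirror a ~12 h sampling cadence: 13 timepoints over 6 days,
    three replicates. ``noise_cv`` of 0 returns exact model values.
    """
    if times is None:
        times = np.arange(0.0, 145.0, 12.0)  # 13 points, 0-144 h
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    model = logistic_density(times, K, P0, T)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    series = []
    for rep in range(replicates):
        noise = (np.exp(rng.normal(0.0, sigma, size=times.size))
                 if noise_cv > 0 else np.ones_like(times))
        series.append(GrowthSeries(
            times=tuple(times),
            densities=tuple(model * noise),
            replicate=f"rep{rep + 1}",
        ))
    return series
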