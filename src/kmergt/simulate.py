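"""Diploid SV simulation and wgsim-like paired-end read generation.

Generates the study design used throughout the test suite and the
bundled evaluation protocols: a uniform random reference, a set of
non-overlapping deletions/insertions (optionally inversions) with random
genotypes, the two haplotype sequences implied by those genotypes, and
paired-end reads drawn uniformly from both haplotypes with i.i.d.
substitution errors.  All randomness flows from a single top-level seed.

Two canned protocols reproduce the evaluation design at desk scale:
a training genome restricted to genotypes 0/1 and 1/1 measures the
extraction rate, and an independent test genome with all three
genotypes measures end-to-end genotyping accuracy.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

from .kmers import INVALID_BASE, _BASE_CODE
from .variants import GENOTYPES, Genotype, SVRecord, SVType

logger = logging.getLogger(__name__)

_CODE_TO_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)

TRAINING_GENOTYPES = (Genotype.HET, Genotype.HOM_ALT)
TEST_GENOTYPES = GENOTYPES


@dataclass
class SimulationConfig:
    """Study conditions for one simulated sample.

    Defaults replicate the desk-scale evaluation protocol: a 5 Mb
    reference carrying 300 insertions/deletions of 50-500 bp, sequenced
    at 30x with 100 bp paired reads, 400+/-50 bp fragments and a 0.1%
    substitution error rate.
    """

    genome_length: int = 5_000_000
    n_svs: int = 300
    sv_length_range: tuple[int, int] = (50, 500)
    svtype_mix: dict = field(
        default_factory=lambda: {SVType.DEL: 0.5, SVType.INS: 0.5}
    )
    coverage: float = 30.0
    read_length: int = 100
    fragment_mean: float = 400.0
    fragment_sd: float = 50.0
    base_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if min(self.sv_length_range) < 1 or self.coverage <= 0:
            raise ValueError("sv lengths and coverage must be positive")


def _derive_seed(seed: int, salt: int) -> int:
    return (seed * 1_000_003 + salt) % (2**31)


def codes_to_str(codes: np.ndarray) -> str:
    return _CODE_TO_ASCII[codes].tobytes().decode()


def str_to_codes(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def generate_reference(length: int, seed: int) -> str:
    """Uniform random A/C/G/T sequence, reproducible by seed."""
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    return codes_to_str(rng.integers(0, 4, size=length, dtype=np.uint8))


def random_sv_set(
    ref: str,
    config: SimulationConfig,
    genotypes: Sequence[Genotype] = TRAINING_GENOTYPES,
    k: int = 32,
    margin: int = 1000,
) -> tuple[list[SVRecord], dict[str, Genotype]]:
    """Place non-overlapping SVs with random genotypes on one contig.

    Footprints are separated by at least 2k bases so no two SVs compete
    for the same junction k-mers.  Training simulations restrict
    genotypes to 0/1 and 1/1 (every SV present on the sample); test
    simulations allow 0/0 as well (the SV is in the panel but absent
    from the genome).
    """
    rng = np.random.default_rng(_derive_seed(config.seed, 1))
    lo_len, hi_len = config.sv_length_range
    types = sorted(config.svtype_mix, key=lambda t: t.value)
    probs = np.array([config.svtype_mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    min_gap = 2 * k
    placed: list[tuple[int, int]] = []  # sorted footprints
    records: list[SVRecord] = []
    truth: dict[str, Genotype] = {}
    from bisect import bisect_left, insort

    max_tries = 200 * config.n_svs
    tries = 0
    while len(records) < config.n_svs:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {config.n_svs} SVs without overlap"
            )
        svtype = types[int(rng.choice(len(types), p=probs))]
        length = int(rng.integers(lo_len, hi_len + 1))
        start = int(rng.integers(margin, len(ref) - margin - length))
        end = start if svtype is SVType.INS else start + length
        i = bisect_left(placed, (start, end))
        if i > 0 and placed[i - 1][1] + min_gap > start:
            continue
        if i < len(placed) and end + min_gap > placed[i][0]:
            continue
        insort(placed, (start, end))
        sv_id = f"sv{len(records):05d}"
        ins_seq = (
            codes_to_str(rng.integers(0, 4, size=length, dtype=np.uint8))
            if svtype is SVType.INS
            else ""
        )
        records.append(
            SVRecord(sv_id, "chr1", start, end, svtype, inserted_seq=ins_seq)
        )
        truth[sv_id] = Genotype(int(rng.choice([int(g) for g in genotypes])))
    records.sort(key=lambda sv: sv.start)
    return records, truth


@dataclass
class DiploidGenome:
    """Two haplotype sequences (base-code arrays) plus the genotype map."""

    haplotypes: tuple[np.ndarray, np.ndarray]
    truth: dict[str, Genotype]
    chrom: str = "chr1"

    @property
    def total_length(self) -> int:
        return sum(len(h) for h in self.haplotypes)


def build_diploid(
    ref: str,
    svs: Sequence[SVRecord],
    genotypes: dict[str, Genotype],
    seed: int = 0,
) -> DiploidGenome:
    """Apply SVs to a reference: 1/1 on both haplotypes, 0/1 on one
    (chosen at random), 0/0 on neither."""
    ordered = sorted(svs, key=lambda sv: sv.start)
    for a, b in zip(ordered, ordered[1:]):
        if a.end > b.start:
            raise ValueError(f"overlapping SVs {a.id} and {b.id}")
    rng = np.random.default_rng(_derive_seed(seed, 2))
    het_hap = {sv.id: int(rng.integers(0, 2)) for sv in ordered}
    ref_codes = str_to_codes(ref)
    haplotypes = []
    for hap in (0, 1):
        pieces = []
        cursor = 0
        for sv in ordered:
            g = genotypes.get(sv.id, Genotype.HOM_REF)
            carried = g is Genotype.HOM_ALT or (
                g is Genotype.HET and het_hap[sv.id] == hap
            )
            if not carried:
                continue
            pieces.append(ref_codes[cursor : sv.start])
            if sv.svtype is SVType.DEL:
                pass
            elif sv.svtype is SVType.INS:
                pieces.append(str_to_codes(sv.inserted_seq))
            else:  # INV: reverse complement in place
                seg = ref_codes[sv.start : sv.end]
                pieces.append((3 - seg)[::-1])
            cursor = sv.end
        pieces.append(ref_codes[cursor:])
        haplotypes.append(np.concatenate(pieces) if len(pieces) > 1 else pieces[0].copy())
    return DiploidGenome(
        haplotypes=(haplotypes[0], haplotypes[1]), truth=dict(genotypes)
    )


class ReadSimulator:
    """Paired-end reads from a diploid genome, generated lazily in chunks.

    Fragments are drawn uniformly from both haplotypes (coverage equal
    in expectation), mate 2 is the reverse complement of the fragment
    end, and substitution errors are applied per base.  The number of
    pairs is coverage x total_diploid_length / (2 x 2 x read_length), so
    each genomic locus (two haplotype copies) is covered ``coverage``
    times in expectation.  Re-iterating :meth:`chunks` regenerates the
    identical reads from the stored seed.
    """

    CHUNK_PAIRS = 65_536

    def __init__(self, diploid: DiploidGenome, config: SimulationConfig):
        self.diploid = diploid
        self.config = config
        self.n_pairs = int(
            round(
                config.coverage
                * diploid.total_length
                / (2 * 2 * config.read_length)
            )
        )
        for h in diploid.haplotypes:
            if len(h) < config.read_length:
                raise ValueError("haplotype shorter than read length")

    def chunks(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield (mate1, mate2) base-code matrices of up to CHUNK_PAIRS rows."""
        cfg = self.config
        rng = np.random.default_rng(_derive_seed(cfg.seed, 3))
        h1, h2 = self.diploid.haplotypes
        lens = np.array([len(h1), len(h2)], dtype=float)
        L = cfg.read_length
        remaining = self.n_pairs
        while remaining > 0:
            n = min(self.CHUNK_PAIRS, remaining)
            remaining -= n
            hap_pick = rng.random(n) < lens[0] / lens.sum()
            flen = np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, n)).astype(
                np.int64
            )
            m1 = np.empty((n, L), dtype=np.uint8)
            m2 = np.empty((n, L), dtype=np.uint8)
            for hap_idx, hap in ((0, h1), (1, h2)):
                sel = np.nonzero(hap_pick == (hap_idx == 0))[0]
                if sel.size == 0:
                    continue
                fl = np.clip(flen[sel], L, len(hap))
                start = (rng.random(sel.size) * (len(hap) - fl + 1)).astype(np.int64)
                idx1 = start[:, None] + np.arange(L)
                m1[sel] = hap[idx1]
                idx2 = (start + fl - L)[:, None] + np.arange(L)
                m2[sel] = (3 - hap[idx2])[:, ::-1]
            if cfg.base_error_rate > 0:
                for m in (m1, m2):
                    err = rng.random(m.shape) < cfg.base_error_rate
                    shift = rng.integers(1, 4, size=m.shape, dtype=np.uint8)
                    m[err] = (m[err] + shift[err]) % 4
            yield m1, m2

    def to_fastq(self, path1: str, path2: str) -> None:
        """Write both mates as FASTQ (gzip if the path ends in .gz)."""
        qual = b"I" * self.config.read_length
        raw = [open(p, "wb") for p in (path1, path2)]
        openers = [
            gzip.GzipFile(filename="", mode="wb", fileobj=fh, mtime=0)
            if str(p).endswith(".gz")
            else fh
            for p, fh in zip((path1, path2), raw)
        ]
        try:
            pair_no = 0
            for m1, m2 in self.chunks():
                for mate, (fh, m) in enumerate(zip(openers, (m1, m2)), start=1):
                    ascii_m = _CODE_TO_ASCII[m]
                    records = []
                    for i in range(m.shape[0]):
                        name = f"@p{pair_no + i}/{mate}\n".encode()
                        records.append(
                            name + ascii_m[i].tobytes() + b"\n+\n" + qual + b"\n"
                        )
                    fh.write(b"".join(records))
                pair_no += m1.shape[0]
        finally:
            for fh in openers:
                fh.close()
            for fh in raw:
                fh.close()


def simulate_reads(diploid: DiploidGenome, config: SimulationConfig) -> ReadSimulator:
    return ReadSimulator(diploid, config)


def simulate_sample(
    config: SimulationConfig,
    genotypes: Sequence[Genotype] = TRAINING_GENOTYPES,
    svs: Optional[Sequence[SVRecord]] = None,
    truth: Optional[dict[str, Genotype]] = None,
    ref: Optional[str] = None,
    k: int = 32,
):
    """Reference + SV set + diploid genome + read simulator in one call.

    Pass ``svs`` (and optionally a fresh ``truth``) to re-genotype an
    existing SV set on a new sample, as the test stage of the evaluation
    protocol does.
    """
    if ref is None:
        ref = generate_reference(config.genome_length, _derive_seed(config.seed, 0))
    if svs is None:
        svs, truth = random_sv_set(ref, config, genotypes, k=k)
    elif truth is None:
        rng = np.random.default_rng(_derive_seed(config.seed, 4))
        truth = {
            sv.id: Genotype(int(rng.choice([int(g) for g in genotypes])))
            for sv in svs
        }
    diploid = build_diploid(ref, svs, truth, seed=config.seed)
    reads = simulate_reads(diploid, config)
    return ref, list(svs), dict(truth), diploid, reads


def extraction_rate_protocol(
    seed: int,
    coverage: float = 30.0,
    config: Optional[SimulationConfig] = None,
    k: int = 32,
    n_control: int = 10_000,
):
    """Training-stage protocol: simulate, extract, report the extraction rate.

    Returns ``(panel, report)`` where ``report['rate']`` is the fraction
    of SVs retaining at least one k-mer after all filters.
    """
    from .extraction import TrainingSample, extract_panel

    cfg = config or SimulationConfig(seed=seed, coverage=coverage)
    cfg = replace(cfg, seed=seed, coverage=coverage)
    ref, svs, truth, diploid, reads = simulate_sample(cfg, TRAINING_GENOTYPES, k=k)
    sample = TrainingSample(reads=reads, truth=truth)
    panel = extract_panel(
        {"chr1": ref}, svs, [sample], k=k, n_control=n_control,
        seed=_derive_seed(seed, 5),
    )
    report = {
        "rate": panel.extraction_rate,
        "n_svs": len(svs),
        "n_with_kmers": sum(1 for n in panel.n_kmers_per_sv().values() if n > 0),
        "n_kmers": len(panel.profiles),
    }
    return panel, report


def end_to_end_protocol(
    seed: int,
    coverage: float = 30.0,
    config: Optional[SimulationConfig] = None,
    k: int = 32,
    n_control: int = 10_000,
):
    """Full two-stage protocol: extract on a training sample, genotype an
    independent test sample carrying the same SVs with all three
    genotypes, and score the calls.

    Returns ``(panel, calls, test_truth, metrics)``.
    """
    from .genotyping import evaluate_calls, genotype_sample

    cfg = config or SimulationConfig(seed=seed, coverage=coverage)
    cfg = replace(cfg, seed=seed, coverage=coverage)
    panel, _ = extraction_rate_protocol(seed, coverage, cfg, k=k, n_control=n_control)
    test_cfg = replace(cfg, seed=_derive_seed(seed, 7))
    ref = generate_reference(cfg.genome_length, _derive_seed(cfg.seed, 0))
    _, svs, test_truth, diploid, test_reads = simulate_sample(
        test_cfg, TEST_GENOTYPES, svs=panel.svs, ref=ref, k=k
    )
    calls, stats = genotype_sample(panel, test_reads)
    metrics = evaluate_calls(calls, test_truth)
    return panel, calls, test_truth, metrics
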