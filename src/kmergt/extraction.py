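"""Selection and filtering of the k-mers that represent each SV.

The panel for an SV is drawn from two sources: splicing the alternate
haplotype out of the reference around the breakpoints (junction k-mers,
plus inner k-mers from deleted or inserted sequence), and, when
alignments of a training sample are available, the soft-clipped parts of
reads mapping near the breakpoints.  Candidates then pass three filters:

1. reference occurrences — a k-mer is kept only if every occurrence in
   the reference lies inside the footprint of some input SV (alt-derived
   k-mers must not occur at all outside; ref-derived k-mers must occur
   exactly once, at their own locus);
2. cross-SV deduplication — any k-mer claimed by more than one SV is
   dropped from all of them;
3. training concordance — each k-mer, used alone, must predict the known
   genotype of its SV in every training sample where that genotype is
   known.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import kmers
from .kmers import KmerIndex, canonical, count_reads, encode_kmer, scan_positions
from .variants import (
    ALT_ROLES,
    GENOTYPES,
    JUNCTION_ROLES,
    REF_ROLES,
    ROLE_CONTROL,
    ROLE_INNER_ALT,
    ROLE_INNER_REF,
    ROLE_JUNCTION_ALT,
    ROLE_JUNCTION_REF,
    Genotype,
    SVRecord,
    SVType,
    expected_copy_table,
    revcomp,
)

logger = logging.getLogger(__name__)

DEFAULT_K = 32
MAX_KMERS_PER_SV = 64
DEFAULT_SEARCH_RADIUS = 100
DEFAULT_N_CONTROL = 10_000
CONTROL_SV_ID = "*"


@dataclass(frozen=True)
class KmerProfile:
    """A selected k-mer: its canonical code, role, SV, stored neighbors
    (canonical codes of the windows one base left/right in the source
    haplotype; None at sequence edges) and expected copy number per
    genotype as ``(copies_00, copies_01, copies_11)``."""

    code: int
    k: int
    sv_id: str
    role: str
    left_neighbor: Optional[int]
    right_neighbor: Optional[int]
    copies: tuple[int, int, int]

    def copy_for(self, genotype: Genotype) -> int:
        return self.copies[int(genotype)]

    @property
    def is_junction(self) -> bool:
        return self.role in JUNCTION_ROLES


@dataclass
class TrainingSample:
    """A sample with known SV genotypes used to vet candidate k-mers.

    ``reads`` is anything :func:`kmergt.kmers.count_reads` accepts; SVs
    absent from ``truth`` are treated as unknown and skipped by the
    concordance filter.
    """

    reads: object
    truth: dict[str, Genotype]
    stats: Optional[object] = None
    alignments: Optional[str] = None


def build_index(profiles: Iterable[KmerProfile], k: int) -> KmerIndex:
    """Counting index over profiles, neighbor sets merged per code."""
    index = KmerIndex(k)
    for p in profiles:
        index.add(p.code, [n for n in (p.left_neighbor, p.right_neighbor) if n is not None])
    return index


def _copies_tuple(role: str, svtype: SVType) -> tuple[int, int, int]:
    table = expected_copy_table(role, svtype)
    return tuple(table[g] for g in GENOTYPES)


def _window_profile(
    source: str, s: int, k: int, sv_id: str, role: str, copies: tuple[int, int, int]
) -> Optional[KmerProfile]:
    code = encode_kmer(source[s : s + k])
    if code is None:
        return None
    left = encode_kmer(source[s - 1 : s - 1 + k]) if s >= 1 else None
    right = encode_kmer(source[s + 1 : s + 1 + k]) if s + 1 + k <= len(source) else None
    return KmerProfile(
        code=canonical(code, k),
        k=k,
        sv_id=sv_id,
        role=role,
        left_neighbor=canonical(left, k) if left is not None else None,
        right_neighbor=canonical(right, k) if right is not None else None,
        copies=copies,
    )


def candidates_from_reference(
    ref_seq: str, sv: SVRecord, k: int, flank: Optional[int] = None
) -> set[KmerProfile]:
    """Candidate k-mers for one SV derived from the reference sequence.

    Emits alt-junction k-mers (windows of the spliced alternate
    haplotype straddling a novel junction), ref-junction k-mers (windows
    of the reference straddling a breakpoint, destroyed by the SV),
    inner-ref k-mers for deletions and inner-alt k-mers for insertions.
    An SV shorter than k simply yields no inner k-mers.
    """
    if flank is None:
        flank = k  # one base beyond the k-1 minimum keeps both neighbors
    if flank < k - 1:
        raise ValueError("flank must be at least k-1 for junction k-mers")
    if sv.span == 0 and not sv.inserted_seq:
        return set()  # identity haplotype: nothing is created or destroyed

    out: dict[int, KmerProfile] = {}

    def add(source: str, s: int, role: str, copies) -> None:
        if s < 0 or s + k > len(source):
            return
        p = _window_profile(source, s, k, sv.id, role, copies)
        if p is not None and p.code not in out:
            out[p.code] = p

    # --- alternate haplotype ---
    left_len = min(flank, sv.start)
    alt = _splice(ref_seq, sv, flank)
    if sv.svtype is SVType.DEL:
        junctions = [left_len]
    else:  # INS and INV create two novel junctions
        mid_len = len(sv.inserted_seq) if sv.svtype is SVType.INS else sv.span
        junctions = [left_len, left_len + mid_len]
    copies_alt = _copies_tuple(ROLE_JUNCTION_ALT, sv.svtype)
    for j in junctions:
        for s in range(j - k + 1, j):
            add(alt, s, ROLE_JUNCTION_ALT, copies_alt)
    if sv.svtype is SVType.INS and len(sv.inserted_seq) >= k:
        copies = _copies_tuple(ROLE_INNER_ALT, sv.svtype)
        for s in range(left_len, left_len + len(sv.inserted_seq) - k + 1):
            add(alt, s, ROLE_INNER_ALT, copies)

    # --- reference haplotype (sequence destroyed by the SV) ---
    breakpoints = [sv.start] if sv.svtype is SVType.INS else [sv.start, sv.end]
    copies_ref = _copies_tuple(ROLE_JUNCTION_REF, sv.svtype)
    for bp in breakpoints:
        for s in range(bp - k + 1, bp):
            add(ref_seq, s, ROLE_JUNCTION_REF, copies_ref)
    if sv.svtype is SVType.DEL and sv.span >= k:
        copies = _copies_tuple(ROLE_INNER_REF, sv.svtype)
        for s in range(sv.start, sv.end - k + 1):
            add(ref_seq, s, ROLE_INNER_REF, copies)

    return set(out.values())


def _splice(ref_seq: str, sv: SVRecord, flank: int) -> str:
    from .variants import alt_haplotype_window

    return alt_haplotype_window(ref_seq, sv, flank)


def candidates_from_clipped_reads(
    alignments,
    sv: SVRecord,
    k: int,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
) -> set[KmerProfile]:
    """Candidate k-mers from soft-clipped reads near an SV's breakpoints.

    Reads crossing a breakpoint are typically soft-clipped by the
    aligner, and the clipped bases spell the alternate haplotype.  Every
    read k-mer overlapping at least one clipped base becomes a
    junction-alt candidate, with neighbors taken from the read itself,
    so this path needs no breakpoint-exact coordinates.

    ``alignments`` is a pysam.AlignmentFile or a path to a SAM/BAM file.
    """
    import pysam

    close = alignments is None
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        close = True
    breakpoints = [sv.start] if sv.svtype is SVType.INS else [sv.start, sv.end]
    copies = _copies_tuple(ROLE_JUNCTION_ALT, sv.svtype)
    out: dict[int, KmerProfile] = {}
    try:
        reads = _fetch_near(alignments, sv.chrom, breakpoints, search_radius)
        n_clipped = 0
        for aln in reads:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            seq = aln.query_sequence
            if not seq or aln.cigartuples is None:
                continue
            for clip_start, clip_end, clip_point in _soft_clips(aln):
                if not any(abs(clip_point - bp) <= search_radius for bp in breakpoints):
                    continue
                n_clipped += 1
                lo = max(0, clip_start - k + 1)
                hi = min(len(seq) - k, clip_end - 1)
                for s in range(lo, hi + 1):
                    p = _window_profile(seq, s, k, sv.id, ROLE_JUNCTION_ALT, copies)
                    if p is not None and p.code not in out:
                        out[p.code] = p
        if n_clipped == 0:
            logger.warning("%s: no soft-clipped reads near breakpoints", sv.id)
    finally:
        if close:
            alignments.close()
    return set(out.values())


def _fetch_near(alignments, chrom, breakpoints, radius):
    lo = max(0, min(breakpoints) - radius)
    hi = max(breakpoints) + radius
    try:
        return list(alignments.fetch(chrom, lo, hi))
    except (ValueError, OSError):
        # no index (e.g. plain SAM): fall back to a full scan
        out = []
        for aln in alignments.fetch(until_eof=True):
            if aln.reference_name == chrom and not aln.is_unmapped:
                if aln.reference_start <= hi and aln.reference_end >= lo:
                    out.append(aln)
        return out


def _soft_clips(aln):
    """Soft-clipped segments of a read: (read_start, read_end, ref_point)."""
    cig = aln.cigartuples
    read_len = aln.query_length or len(aln.query_sequence or "")
    out = []
    if cig[0][0] == 4:  # leading soft clip: clip point at alignment start
        out.append((0, cig[0][1], aln.reference_start))
    if cig[-1][0] == 4:  # trailing soft clip: clip point at alignment end
        out.append((read_len - cig[-1][1], read_len, aln.reference_end))
    return out


def _merged_footprints(
    svs: Sequence[SVRecord], k: int
) -> dict[str, tuple[list[int], list[int]]]:
    """Per-chromosome merged intervals of window starts near any SV."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for sv in svs:
        lo = sv.start - (k - 1)
        hi = sv.end + (k - 1)  # inclusive bound on window starts
        by_chrom.setdefault(sv.chrom, []).append((lo, hi))
    out = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        merged = [list(ivals[0])]
        for lo, hi in ivals[1:]:
            if lo <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        out[chrom] = ([m[0] for m in merged], [m[1] for m in merged])
    return out


def _in_intervals(pos: int, los: list[int], his: list[int]) -> bool:
    i = bisect_right(los, pos) - 1
    return i >= 0 and pos <= his[i]


def filter_reference_occurrences(
    candidates: Iterable[KmerProfile],
    ref: Mapping[str, str],
    all_svs: Sequence[SVRecord],
    k: int,
) -> set[KmerProfile]:
    """Drop candidates that occur in reference loci no SV touches.

    Alt-derived k-mers must have zero reference occurrences outside SV
    footprints (SV interval +/- k-1).  Ref-derived k-mers must occur
    exactly once in the reference, at their own SV's locus — the
    defining property of a unique k-mer whose count tracks depth.
    """
    candidates = list(candidates)
    if not candidates:
        return set()
    footprints = _merged_footprints(all_svs, k)
    sv_by_id = {sv.id: sv for sv in all_svs}
    codes = {p.code for p in candidates}
    occ: dict[int, list[tuple[str, int]]] = {c: [] for c in codes}
    for chrom, seq in ref.items():
        for code, positions in scan_positions(seq, codes, k).items():
            for pos in positions:
                occ[code].append((chrom, pos))
    kept: set[KmerProfile] = set()
    n_drop_alt = n_drop_ref = 0
    for p in candidates:
        hits = occ[p.code]
        if p.role in ALT_ROLES:
            ok = all(
                chrom in footprints and _in_intervals(pos, *footprints[chrom])
                for chrom, pos in hits
            )
            if not ok:
                n_drop_alt += 1
                continue
        else:  # ref-derived: unique, at its own locus
            sv = sv_by_id[p.sv_id]
            own_lo, own_hi = sv.start - (k - 1), sv.end + (k - 1)
            ok = (
                len(hits) == 1
                and hits[0][0] == sv.chrom
                and own_lo <= hits[0][1] <= own_hi
            )
            if not ok:
                n_drop_ref += 1
                continue
        kept.add(p)
    logger.info(
        "reference-occurrence filter: kept %d/%d (dropped %d alt with off-target "
        "hits, %d ref not unique)",
        len(kept), len(candidates), n_drop_alt, n_drop_ref,
    )
    return kept


def deduplicate_across_svs(candidates: Iterable[KmerProfile]) -> set[KmerProfile]:
    """Drop any k-mer claimed by more than one SV (from all claimants)."""
    candidates = list(candidates)
    owners: dict[int, set[str]] = {}
    for p in candidates:
        owners.setdefault(p.code, set()).add(p.sv_id)
    kept = {p for p in candidates if len(owners[p.code]) == 1}
    if len(kept) < len(candidates):
        logger.info(
            "cross-SV dedup: dropped %d shared k-mers", len(candidates) - len(kept)
        )
    return kept


def select_control_kmers(
    ref: Mapping[str, str],
    svs: Sequence[SVRecord],
    k: int,
    n: int = DEFAULT_N_CONTROL,
    rng: Optional[np.random.Generator] = None,
) -> list[KmerProfile]:
    """Sample unique reference k-mers outside every SV footprint.

    These serve as the depth controls from which a sample's mu and
    sigma^2 are estimated: verified to occur exactly once in the
    reference and untouched by any input SV, their diploid copy number
    is 2 in every sample.
    """
    rng = rng or np.random.default_rng(0)
    footprints = _merged_footprints(svs, k)
    chroms = [c for c, s in ref.items() if len(s) >= k]
    lengths = np.array([len(ref[c]) - k + 1 for c in chroms], dtype=float)
    if not chroms:
        raise ValueError("reference shorter than k")
    candidates: dict[int, tuple[str, int]] = {}
    attempts = 0
    while len(candidates) < 3 * n and attempts < 10:
        attempts += 1
        m = 4 * n
        picks = rng.choice(len(chroms), size=m, p=lengths / lengths.sum())
        for ci in picks:
            chrom = chroms[ci]
            pos = int(rng.integers(1, len(ref[chrom]) - k))
            if chrom in footprints and _in_intervals(pos, *footprints[chrom]):
                continue
            code = encode_kmer(ref[chrom][pos : pos + k])
            if code is None:
                continue
            candidates.setdefault(canonical(code, k), (chrom, pos))
    occ_total: dict[int, int] = {c: 0 for c in candidates}
    for chrom, seq in ref.items():
        for code, positions in scan_positions(seq, candidates.keys(), k).items():
            occ_total[code] += len(positions)
    controls = []
    for code, (chrom, pos) in candidates.items():
        if occ_total[code] != 1:
            continue
        p = _window_profile(
            ref[chrom], pos, k, CONTROL_SV_ID, ROLE_CONTROL, (2, 2, 2)
        )
        if p is not None:
            controls.append(p)
        if len(controls) >= n:
            break
    if len(controls) < min(n, 100):
        logger.warning("only %d control k-mers could be selected", len(controls))
    return controls


def filter_by_training_genotype(
    candidates: Iterable[KmerProfile],
    training_samples: Sequence[TrainingSample],
    controls: Sequence[KmerProfile],
    k: int,
    verify_neighbors: bool = True,
) -> set[KmerProfile]:
    """Keep k-mers that, used alone, reproduce each training genotype.

    For every training sample the candidates (plus controls) are counted
    in the reads, the sample's depth model is estimated from the control
    counts, and each candidate's single-k-mer maximum-likelihood
    genotype is compared with the known genotype of its SV.  A candidate
    survives only if it agrees in every sample where the genotype is
    known; SVs with unknown genotype everywhere pass vacuously.
    """
    from .genotyping import best_genotype, estimate_sample_stats, single_kmer_loglik

    survivors = list(candidates)
    for si, sample in enumerate(training_samples):
        index = build_index(list(survivors) + list(controls), k)
        table = count_reads(sample.reads, index, verify_neighbors)
        sample.stats = estimate_sample_stats([table[p.code] for p in controls])
        kept = []
        n_drop = 0
        for p in survivors:
            truth = sample.truth.get(p.sv_id)
            if truth is None:
                kept.append(p)
                continue
            predicted = best_genotype(single_kmer_loglik(table[p.code], p, sample.stats))
            if predicted == truth:
                kept.append(p)
            else:
                n_drop += 1
        logger.info(
            "training sample %d (mu=%.2f, sigma2=%.2f): dropped %d/%d discordant "
            "k-mers", si, sample.stats.mu, sample.stats.sigma2, n_drop, len(survivors),
        )
        survivors = kept
    return set(survivors)


def cap_per_sv(
    profiles: Iterable[KmerProfile], max_per_sv: int = MAX_KMERS_PER_SV
) -> list[KmerProfile]:
    """Keep at most ``max_per_sv`` k-mers per SV, junctions preferred."""
    by_sv: dict[str, list[KmerProfile]] = {}
    for p in profiles:
        by_sv.setdefault(p.sv_id, []).append(p)
    out: list[KmerProfile] = []
    for sv_id in sorted(by_sv):
        group = sorted(by_sv[sv_id], key=lambda p: (not p.is_junction, p.code))
        out.extend(group[:max_per_sv])
    return out


@dataclass
class Panel:
    """The exported product of extraction: per-SV k-mers plus controls.

    Self-contained for genotyping any new sample: SV records provide
    output coordinates, controls provide the depth model.
    """

    k: int
    svs: list[SVRecord]
    profiles: list[KmerProfile]
    controls: list[KmerProfile]

    def n_kmers_per_sv(self) -> dict[str, int]:
        counts = {sv.id: 0 for sv in self.svs}
        for p in self.profiles:
            counts[p.sv_id] = counts.get(p.sv_id, 0) + 1
        return counts

    @property
    def extraction_rate(self) -> float:
        """Fraction of input SVs that retained at least one k-mer."""
        per_sv = self.n_kmers_per_sv()
        if not per_sv:
            return 0.0
        return sum(1 for n in per_sv.values() if n > 0) / len(per_sv)


def extract_panel(
    ref: Mapping[str, str],
    svs: Sequence[SVRecord],
    training_samples: Sequence[TrainingSample],
    k: int = DEFAULT_K,
    n_control: int = DEFAULT_N_CONTROL,
    max_per_sv: int = MAX_KMERS_PER_SV,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    verify_neighbors: bool = True,
    seed: int = 0,
) -> Panel:
    """Run the full k-mer extraction phase and return the panel.

    Reference-derived candidates are generated for every SV; clipped-read
    candidates are added for training samples that carry alignments.
    Candidates then pass the reference-occurrence, cross-SV-dedup and
    training-concordance filters, and finally the per-SV cap.
    """
    candidates: dict[tuple[int, str], KmerProfile] = {}
    for sv in svs:
        if sv.chrom not in ref:
            raise ValueError(f"{sv.id}: unknown contig {sv.chrom!r}")
        if sv.svtype is SVType.INS and not sv.inserted_seq and not any(
            s.alignments for s in training_samples
        ):
            raise ValueError(
                f"{sv.id}: insertion without sequence requires training alignments"
            )
        found = candidates_from_reference(ref[sv.chrom], sv, k) if (
            sv.inserted_seq or sv.svtype is not SVType.INS
        ) else set()
        for sample in training_samples:
            if sample.alignments:
                found |= candidates_from_clipped_reads(
                    sample.alignments, sv, k, search_radius
                )
        for p in found:
            candidates.setdefault((p.code, p.sv_id), p)
    logger.info("collected %d candidate k-mers for %d SVs", len(candidates), len(svs))

    kept = filter_reference_occurrences(candidates.values(), ref, svs, k)
    kept = deduplicate_across_svs(kept)
    rng = np.random.default_rng(seed)
    controls = select_control_kmers(ref, svs, k, n_control, rng)
    kept = filter_by_training_genotype(
        kept, training_samples, controls, k, verify_neighbors
    )
    final = cap_per_sv(kept, max_per_sv)
    panel = Panel(k=k, svs=list(svs), profiles=final, controls=controls)
    logger.info(
        "panel: %d k-mers, %d controls, extraction rate %.2f%%",
        len(final), len(controls), 100 * panel.extraction_rate,
    )
    return panel
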