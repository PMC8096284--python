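"""Genotype likelihoods from k-mer counts under a normal depth model.

The count of a k-mer unique in a diploid genome (copy number 2) is the
sum of the reads drawn from each haplotype and is modelled as
N(mu, sigma^2), with mu and sigma^2 estimated sample-wide from a panel
of control k-mers known to be unique and unaffected by any input SV.
Assuming equal coverage of the two haplotypes, a k-mer on a single
haplotype (copy 1) follows N(mu/2, sigma^2/2), and a k-mer absent from
the genome (copy 0) is modelled with mean zero and a small fixed
variance.  Per-SV genotype likelihoods multiply the per-k-mer densities
under an independence approximation, and the maximum-likelihood genotype
is called.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .variants import GENOTYPES, Genotype

MU_FLOOR = 0.1
SIGMA2_FLOOR = 1.0
#: per-k-mer counts are capped at COUNT_CAP * mu before likelihood
#: evaluation, damping repetitive k-mers that escaped filtering
COUNT_CAP = 2.0


@dataclass
class SampleStats:
    """Sample-wide depth model: moments of unique (copy-2) k-mer counts."""

    mu: float
    sigma2: float
    n_control: int


def estimate_sample_stats(
    control_counts: Sequence[int],
    trim: float = 0.025,
    mu_floor: float = MU_FLOOR,
    sigma2_floor: float = SIGMA2_FLOOR,
) -> SampleStats:
    """Estimate mu and sigma^2 from control k-mer counts.

    The top and bottom ``trim`` fraction of counts are discarded before
    taking the sample mean and variance, guarding against control k-mers
    that are not actually unique in this sample's genome.
    """
    counts = np.asarray(control_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 control counts")
    if not np.any(counts > 0):
        raise ValueError(
            "all control k-mer counts are zero: reads do not match the panel"
        )
    trimmed = sps.trimboth(counts, trim)
    mu = max(float(np.mean(trimmed)), mu_floor)
    sigma2 = max(float(np.var(trimmed, ddof=1)), sigma2_floor)
    return SampleStats(mu=mu, sigma2=sigma2, n_control=int(counts.size))


def genotype_distribution(copy: int, stats: SampleStats) -> tuple[float, float]:
    """(mean, variance) of a k-mer's count given its diploid copy number."""
    if copy == 2:
        return stats.mu, stats.sigma2
    if copy == 1:
        return stats.mu / 2.0, stats.sigma2 / 2.0
    if copy == 0:
        return 0.0, max(1.0, (stats.mu / 10.0) ** 2)
    raise ValueError(f"copy number must be 0, 1 or 2, got {copy}")


def single_kmer_loglik(
    count: int, profile, stats: SampleStats, count_cap: float = COUNT_CAP
) -> dict[Genotype, float]:
    """Log-likelihood of each genotype from one k-mer's count.

    Evaluates the normal log-density of the (capped) count under the
    genotype's expected copy number from the profile's copy table.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    c = min(float(count), count_cap * stats.mu) if count_cap else float(count)
    out: dict[Genotype, float] = {}
    for g in GENOTYPES:
        mean, var = genotype_distribution(profile.copy_for(g), stats)
        out[g] = -0.5 * (math.log(2.0 * math.pi * var) + (c - mean) ** 2 / var)
    return out


def best_genotype(loglik: Mapping[Genotype, float]) -> Genotype:
    """Argmax genotype; exact ties break toward fewer alternate alleles."""
    best = Genotype.HOM_REF
    for g in GENOTYPES:
        if loglik[g] > loglik[best]:
            best = g
    return best


@dataclass
class GenotypeCall:
    """Per-SV genotyping result.

    ``genotype`` is ``None`` (missing) when the SV has no supporting
    k-mers in the panel; otherwise it maximizes ``loglik``.
    """

    sv_id: str
    genotype: Optional[Genotype]
    loglik: Optional[dict[Genotype, float]]
    n_kmers: int

    @property
    def is_missing(self) -> bool:
        return self.genotype is None

    @property
    def is_positive(self) -> bool:
        return self.genotype in (Genotype.HET, Genotype.HOM_ALT)


def call_genotype(
    sv_profiles: Sequence, counts: Mapping[int, int], stats: SampleStats
) -> GenotypeCall:
    """Maximum-likelihood genotype of one SV from its k-mers' counts.

    Per-genotype log-likelihoods are summed over the SV's distinct
    k-mers (independence approximation of the joint count probability).
    """
    seen: set[int] = set()
    total = {g: 0.0 for g in GENOTYPES}
    n = 0
    sv_id = None
    for p in sv_profiles:
        if sv_id is None:
            sv_id = p.sv_id
        elif p.sv_id != sv_id:
            raise ValueError("profiles from more than one SV")
        if p.code in seen:
            continue
        seen.add(p.code)
        ll = single_kmer_loglik(counts[p.code], p, stats)
        for g in GENOTYPES:
            total[g] += ll[g]
        n += 1
    if n == 0:
        return GenotypeCall(sv_id=sv_id or "", genotype=None, loglik=None, n_kmers=0)
    return GenotypeCall(
        sv_id=sv_id, genotype=best_genotype(total), loglik=total, n_kmers=n
    )


@dataclass
class Metrics:
    """Genotyping accuracy over a truth set.

    tgr: exactly-correct genotype calls over all input events.
    fgr: wrong genotype calls over calls made (missing = no call).
    precision/recall: presence-level — a true positive is a positive
    call (0/1 or 1/1) on an event whose true genotype is positive.
    """

    tgr: float
    fgr: float
    precision: float
    recall: float
    n_events: int
    n_calls: int
    n_correct: int
    n_false: int
    n_positive_calls: int
    n_true_positive: int
    n_truth_positive: int


def evaluate_calls(
    calls: Iterable[GenotypeCall], truth: Mapping[str, Genotype]
) -> Metrics:
    """Score genotype calls against known genotypes.

    Events are the keys of ``truth``; calls for unknown events are
    ignored, events without a (non-missing) call count as non-calls.
    """
    if not truth:
        raise ValueError("empty truth set")
    by_id = {c.sv_id: c for c in calls if not c.is_missing}
    n_events = len(truth)
    n_calls = n_correct = n_false = 0
    n_pos_calls = n_tp = n_truth_pos = 0
    for sv_id, true_g in truth.items():
        truth_positive = true_g in (Genotype.HET, Genotype.HOM_ALT)
        if truth_positive:
            n_truth_pos += 1
        call = by_id.get(sv_id)
        if call is None:
            continue
        n_calls += 1
        if call.genotype == true_g:
            n_correct += 1
        else:
            n_false += 1
        if call.is_positive:
            n_pos_calls += 1
            if truth_positive:
                n_tp += 1
    return Metrics(
        tgr=n_correct / n_events,
        fgr=n_false / n_calls if n_calls else 0.0,
        precision=n_tp / n_pos_calls if n_pos_calls else 0.0,
        recall=n_tp / n_truth_pos if n_truth_pos else 0.0,
        n_events=n_events,
        n_calls=n_calls,
        n_correct=n_correct,
        n_false=n_false,
        n_positive_calls=n_pos_calls,
        n_true_positive=n_tp,
        n_truth_positive=n_truth_pos,
    )


def genotype_sample(
    panel, reads, verify_neighbors: bool = True
) -> tuple[list[GenotypeCall], SampleStats]:
    """Genotype every SV of a panel on a raw read stream.

    Counts panel and control k-mers in one pass, estimates the sample's
    depth model from the control counts, then calls each SV.  SVs that
    retained no k-mers at extraction are reported as missing.
    """
    from .extraction import build_index  # local import avoids a cycle

    index = build_index(panel.profiles + panel.controls, panel.k)
    table = count_reads_for_panel(reads, index, verify_neighbors)
    stats = estimate_sample_stats([table[p.code] for p in panel.controls])
    by_sv: dict[str, list] = {sv.id: [] for sv in panel.svs}
    for p in panel.profiles:
        by_sv.setdefault(p.sv_id, []).append(p)
    calls = []
    for sv in panel.svs:
        profiles = by_sv[sv.id]
        if profiles:
            calls.append(call_genotype(profiles, table, stats))
        else:
            calls.append(GenotypeCall(sv_id=sv.id, genotype=None, loglik=None, n_kmers=0))
    return calls, stats


def count_reads_for_panel(reads, index, verify_neighbors: bool = True):
    from .kmers import count_reads

    return count_reads(reads, index, verify_neighbors)
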