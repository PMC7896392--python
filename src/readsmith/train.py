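"""Training: from mapped reads and a reference to a simulation profile.

Pipeline: adapter detection -> pileup and systematic-error calling ->
low-quality-site exclusion -> coverage-bias fits on the selected
(sequence, fragment length) schedule -> corrected counts and the
reference/length-bias iteration -> margin accumulation -> conditional-model
fitting by iterative proportional fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .adapters import (
    AdapterSet, collect_unmapped_kmers, infer_adapter_set,
)
from .covmodel import (
    combine_fits, estimate_bias_sum, fit_gc_flank, fit_ref_len_bias,
    interpolate_len_bias, select_fits,
)
from .genome import Genome
from .margins import MarginSet
from .records import ReadRecord
from .sim import DegenerateSampler, SimProfile, make_sampler
from .stats import (
    MarginStatistics, build_pileup, classify_systematic, corrected_counts,
    enumerate_sites, exclude_low_quality_sites, fill_margins, load_read_batch,
)

logger = logging.getLogger(__name__)

#: dense-cell caps used when converting margins to conditional models
CELL_CAP_TEMPLATE = 1_000_000
CELL_CAP_READ = 2_000_000


@dataclass
class TrainingReport:
    """Per-stage summaries logged by :func:`train_profile`."""

    n_reads: int = 0
    n_pairs: int = 0
    n_systematic: int = 0
    n_tested: int = 0
    n_fits: int = 0
    n_converged: int = 0
    adapters_inferred: bool = False


def _adapter_records(batch, rejected):
    """ReadRecord stream over the unmapped parts feeding adapter inference."""
    rl = batch.read_length
    for i in range(batch.n_reads):
        flen = int(batch.flen[i])
        if 0 < flen < rl:
            yield ReadRecord(
                segment=int(batch.segment[i]), name=f"r{i}",
                bases="".join("ACGTN"[c] for c in batch.bases[i]),
                qualities=[int(q) for q in batch.quals[i]],
                mapped=True, fragment_length=flen,
            )
    for up in rejected:
        if up.bases:
            yield ReadRecord(
                segment=up.segment, name="u", bases=up.bases,
                qualities=[0] * len(up.bases), mapped=False,
            )


def estimate_probabilities(
    ms: MarginStatistics,
    cell_cap_template: int = CELL_CAP_TEMPLATE,
    cell_cap_read: int = CELL_CAP_READ,
    ipf_sweeps: int = 200,
) -> dict:
    """Fit the pairwise-exponential conditional models for all statistics."""
    samplers: dict = {}
    samplers["tendency"] = make_sampler(ms.tendency, cell_cap_template,
                                        degenerate_value=4,
                                        max_sweeps=ipf_sweeps)
    samplers["rate"] = make_sampler(ms.rate, cell_cap_template,
                                    degenerate_value=0,
                                    max_sweeps=ipf_sweeps)
    samplers["seq_quality"] = make_sampler(ms.seq_quality, cell_cap_read,
                                           degenerate_value=30,
                                           max_sweeps=ipf_sweeps)
    bq = {}
    bc = {}
    for key, m in ms.base_quality.items():
        bq[key] = make_sampler(m, cell_cap_read, degenerate_value=30,
                               max_sweeps=ipf_sweeps)
    for key, m in ms.base_call.items():
        bc[key] = make_sampler(m, cell_cap_read, degenerate_value=key[2],
                               max_sweeps=ipf_sweeps)
    samplers["base_quality"] = bq
    samplers["base_call"] = bc
    samplers["indel"] = make_sampler(ms.indel, cell_cap_read,
                                     degenerate_value=0,
                                     max_sweeps=ipf_sweeps)
    ev_margin = ms.indel.one_dim_margin(0) if ms.indel.total > 0 else np.zeros(6)
    samplers["indel_active"] = bool(ev_margin[1:].sum() > 0)
    return samplers


def train_profile(
    sam_path,
    genome: Genome,
    variant_positions: dict | None = None,
    adapter_set: AdapterSet | None = None,
    mq_threshold: int = 10,
    max_fragment_length: int = 1000,
    min_fit_sites: int = 10_000,
    max_fits: int | None = None,
    cell_cap_template: int = CELL_CAP_TEMPLATE,
    cell_cap_read: int = CELL_CAP_READ,
    ipf_sweeps: int = 100,
    report: TrainingReport | None = None,
) -> SimProfile:
    """Train a full simulation profile from a coordinate-sorted SAM/BAM.

    ``variant_positions`` (sequence -> 0-based positions) are excluded from
    every statistic; when no ``adapter_set`` is given, adapters are inferred
    from the 10-mers of unmapped read parts.
    """
    if report is None:
        report = TrainingReport()
    batch, pair_counts, rejected = load_read_batch(
        sam_path, genome, adapter_set=None, mq_threshold=mq_threshold,
    )
    report.n_reads = batch.n_reads
    report.n_pairs = sum(pair_counts.values())

    if adapter_set is None:
        table = collect_unmapped_kmers(_adapter_records(batch, rejected))
        adapter_set = infer_adapter_set(table)
        report.adapters_inferred = adapter_set is not None
        if adapter_set is not None:
            logger.info("inferred adapters: %s / %s",
                        adapter_set.first[0], adapter_set.second[0])
    if adapter_set is not None:
        # reload so soft-clip expansion can honour detected adapters
        batch, pair_counts, rejected = load_read_batch(
            sam_path, genome, adapter_set=adapter_set,
            mq_threshold=mq_threshold,
        )

    pileup = build_pileup(batch, genome, variant_positions)
    sys_profile = classify_systematic(pileup, batch.read_length)
    report.n_systematic = sys_profile.n_systematic
    report.n_tested = sys_profile.n_tested
    logger.info("systematic calls: %d of %d tested positions",
                sys_profile.n_systematic, sys_profile.n_tested)

    exclusions = exclude_low_quality_sites(batch)
    counts_by_seq_len: dict = {}
    for (seq, _start, length, _strand), c in pair_counts.items():
        if length <= max_fragment_length:
            key = (seq, length)
            counts_by_seq_len[key] = counts_by_seq_len.get(key, 0) + c

    summaries = corrected_counts(
        genome, pair_counts, exclusions, adapter_set, rejected,
        max_fragment_length,
    )

    plan = select_fits(genome, counts_by_seq_len)
    if max_fits is not None and len(plan) > max_fits:
        # evenly thinned subset of the schedule (speed/quality trade-off)
        idx = np.unique(np.round(
            np.linspace(0, len(plan) - 1, max_fits)).astype(int))
        plan = [plan[i] for i in idx]
    report.n_fits = len(plan)
    sites = enumerate_sites(genome, pair_counts, exclusions, plan)
    fits = [fit_gc_flank(sd, min_sites=min_fit_sites) for sd in sites]
    report.n_converged = sum(1 for f in fits if f is not None and f.converged)
    logger.info("bias fits: %d scheduled, %d converged",
                report.n_fits, report.n_converged)
    combined = combine_fits(fits)

    bias_sum = estimate_bias_sum(combined, genome, summaries.c_len,
                                 mode="training", exclusions=exclusions)
    b_ref, b_len_sampled = fit_ref_len_bias(summaries, bias_sum)
    combined.b_ref = b_ref
    combined.b_len = interpolate_len_bias(b_len_sampled, summaries.c_len)

    ms = fill_margins(batch, genome, sys_profile, pileup,
                      mq_threshold=mq_threshold)
    samplers = estimate_probabilities(ms, cell_cap_template, cell_cap_read,
                                      ipf_sweeps=ipf_sweeps)

    return SimProfile(
        combined=combined,
        samplers=samplers,
        fragment_length_distribution=summaries.fragment_length_distribution(),
        adapter_set=adapter_set,
        read_length=batch.read_length,
        tiles=list(batch.tiles),
    )
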