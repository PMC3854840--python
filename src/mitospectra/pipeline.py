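"""End-to-end per-sample and cohort analysis orchestration.

Per sample: low-stringency alignment against the reference collects
mtDNA-like reads and yields a sample consensus; reads are re-aligned at
high stringency against that consensus; reads passing low but not high
stringency are routed to split-read breakpoint detection (against the
ALT-rotated reference); broken pairs are excluded from SNV calling;
rearrangement classes are quantified against average coverage.

Per cohort: SNV tables are thresholded, annotated and run-normalized, then
summarised into burdens, biases and linear accumulation-rate models with
young-vs-aged Mann-Whitney comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import align as A
from . import rearrange as RR
from . import snv as SV
from . import spectra as SP
from .reference import CircularGenome, CoordinateMap, RegionAnnotation
from .simulate import ReadPairSet, SampleTruth


@dataclass
class PipelineConfig:
    # the full-DP fallback is unnecessary inside the pipeline: reads it
    # would rescue are junction candidates that belong in the routed set
    aligner: A.AlignerConfig = field(
        default_factory=lambda: A.AlignerConfig(full_scan_fallback=False)
    )
    consensus_max_reads: int = 250_000
    breakpoints: RR.BreakpointConfig = field(default_factory=RR.BreakpointConfig)
    snv: SV.SNVCallParams = field(default_factory=SV.SNVCallParams)
    windows: RR.QuantWindows = field(default_factory=RR.QuantWindows)
    somatic_threshold: float = SV.SOMATIC_THRESHOLD
    normalization_mode: str = "global_mean"
    pivot: int = 577


@dataclass
class SampleResult:
    sample_id: str
    age: float
    cohort: str
    run: str
    consensus: A.ConsensusSequence
    coverage: A.CoverageProfile
    breakpoints: pd.DataFrame
    quant: RR.RearrangementQuant
    snvs: SV.SNVTable
    somatic: pd.DataFrame
    n_reads: int
    n_low: int
    n_high: int
    n_routed: int
    n_broken: int


def run_sample(
    reads: ReadPairSet,
    genome: CircularGenome,
    annot: RegionAnnotation,
    truth: SampleTruth | None = None,
    config: PipelineConfig | None = None,
) -> SampleResult:
    """Run alignment, breakpoint and SNV analysis for one specimen."""
    config = config or PipelineConfig()
    seqs = reads.reads()
    quals = reads.quals()
    L = genome.L

    ref_index = A.ReferenceIndex(genome, config.aligner.word)
    low = A.align_reads(seqs, ref_index, "low", config.aligner)
    if int(low.accepted.sum()) > config.consensus_max_reads:
        # plurality at >1000x is already saturated; cap the consensus input
        sub = low.accepted.copy()
        keep = np.linspace(0, len(seqs) - 1, config.consensus_max_reads).astype(int)
        mask = np.zeros(len(seqs), dtype=bool)
        mask[keep] = True
        sub &= mask
        capped = A.AlignmentSet(
            low.stringency, sub, low.strand, low.ref_start, low.read_start,
            low.length, low.matches, low.columns, low.L,
        )
        capped.read_length = reads.read_length
        cons = A.build_consensus(capped, seqs, genome)
    else:
        cons = A.build_consensus(low, seqs, genome)

    cons_index = A.ReferenceIndex(cons.genome, config.aligner.word)
    high = A.align_reads(seqs, cons_index, "high", config.aligner)
    # the high-stringency pass only considers reads collected at low stringency
    high.accepted &= low.accepted
    broken = A.flag_broken_pairs(high, config.aligner)
    coverage = A.compute_coverage(high)

    routed = np.flatnonzero(low.accepted & ~high.accepted)
    alt_genome = genome.rotated(config.pivot)
    alt_index = A.ReferenceIndex(alt_genome, config.breakpoints.word)
    calls = RR.call_breakpoints(seqs[routed], alt_index, routed, config.breakpoints)
    cmap = CoordinateMap(pivot=config.pivot, L=L)
    bp_df = RR.calls_to_dataframe(calls, cmap)
    bp_df = RR.classify_calls(bp_df, L, config.windows)
    quant = RR.quantify_rearrangements(
        bp_df,
        coverage.average,
        L,
        config.windows,
        read_length=reads.read_length,
        min_segment=config.breakpoints.min_segment,
    )

    snvs = SV.call_snvs(
        high, seqs, quals, cons.genome.codes, exclude=broken, params=config.snv
    )
    annotated = SV.add_annotations(snvs.table, annot)
    somatic = SV.threshold_somatic(annotated, config.somatic_threshold)

    meta = truth or SampleTruth(reads.sample_id, float("nan"), "", "", 0)
    return SampleResult(
        sample_id=reads.sample_id,
        age=meta.age,
        cohort=meta.cohort,
        run=meta.run,
        consensus=cons,
        coverage=coverage,
        breakpoints=bp_df,
        quant=quant,
        snvs=snvs,
        somatic=somatic,
        n_reads=len(seqs),
        n_low=int(low.accepted.sum()),
        n_high=int(high.accepted.sum()),
        n_routed=len(routed),
        n_broken=int(broken[high.accepted].sum()),
    )


@dataclass
class CohortResult:
    samples: list[SampleResult]
    tables: dict[str, pd.DataFrame]  # run-normalized somatic tables
    normalization: SV.RunNormalization
    summaries: pd.DataFrame  # per sample x region burden summary
    rate_models: dict[str, SP.LinearRateModel]
    comparisons: dict[str, SP.CohortComparison]


def summarize_cohort(
    results: list[SampleResult],
    annot: RegionAnnotation,
    normalization_mode: str = "global_mean",
    snv_baseline: float | None = SP.FOREBRAIN_BASELINE_BP,
) -> CohortResult:
    """Normalize runs, summarise burdens and fit accumulation models."""
    tables = {r.sample_id: r.somatic for r in results}
    runs = {r.sample_id: r.run for r in results}
    if len(set(runs.values())) >= 2:
        tables, norm = SV.normalize_runs(tables, runs, mode=normalization_mode)
    else:
        norm = SV.RunNormalization(
            normalization_mode, False, pd.DataFrame({"run": list(set(runs.values())), "offset": 0.0})
        )

    rows = []
    for r in results:
        summ = SP.summarize_spectrum(tables[r.sample_id], annot)
        ts = SP.summarize_spectrum(tables[r.sample_id], annot, transitions_only=True)
        for _, srow in summ.iterrows():
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "age": r.age,
                    "cohort": r.cohort,
                    "run": r.run,
                    "region": srow["region"],
                    "burden_bp": srow["burden_bp"],
                    "burden_mtdna": srow["burden_mtdna"],
                    "transitions_bp": float(
                        ts.loc[ts["region"] == srow["region"], "burden_bp"].iloc[0]
                    ),
                }
            )
    summaries = pd.DataFrame(rows)

    ages = np.array([r.age for r in results], dtype=float)
    models: dict[str, SP.LinearRateModel] = {}
    if len(results) >= 3 and len(np.unique(ages)) >= 2:
        for cls in ("common_deletion", "major_arc", "crm", "crd"):
            y = [r.quant.frequencies_corrected[cls] for r in results]
            models[cls] = SP.fit_rate_model(ages, y)
        allb = summaries[summaries["region"] == "all"]
        models["snv_bp"] = SP.fit_rate_model(
            allb["age"], allb["burden_bp"], baseline=snv_baseline
        )
        models["transitions_bp"] = SP.fit_rate_model(
            allb["age"], allb["transitions_bp"], baseline=snv_baseline
        )
        for region in ("coding", "control"):
            sub = summaries[summaries["region"] == region]
            models[f"transitions_{region}_bp"] = SP.fit_rate_model(
                sub["age"], sub["transitions_bp"]
            )

    comparisons: dict[str, SP.CohortComparison] = {}
    young = [r for r in results if r.cohort == "young"]
    aged = [r for r in results if r.cohort == "aged"]
    if young and aged:
        def grp(vals):
            return SP.mann_whitney_exact(vals[0], vals[1])

        for cls in ("common_deletion", "major_arc", "crm", "crd"):
            comparisons[cls] = grp(
                (
                    [r.quant.frequencies_corrected[cls] for r in young],
                    [r.quant.frequencies_corrected[cls] for r in aged],
                )
            )
        allb = summaries[summaries["region"] == "all"].set_index("sample_id")
        comparisons["snv_bp"] = grp(
            (
                [allb.loc[r.sample_id, "burden_bp"] for r in young],
                [allb.loc[r.sample_id, "burden_bp"] for r in aged],
            )
        )

    return CohortResult(
        samples=results,
        tables=tables,
        normalization=norm,
        summaries=summaries,
        rate_models=models,
        comparisons=comparisons,
    )
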