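"""Quality-filtered low-frequency SNV calling against a sample consensus.

A read contributes a base observation at a position only when the central
base quality exceeds Q33, the mean quality of the +/-5 bp neighbourhood
window exceeds Q30, and the read carries at most two other mismatches or
gaps within that window.  No minimum-count or minimum-coverage filter is
applied: single-read observations are biologically valid in a heteroplasmic
population.  All reads in broken pairs are excluded upstream to suppress
chimeric-fragment artifacts.  Together these filters typically discard a
quarter or so of raw aligned bases ("effective" vs raw coverage).

Frequencies are computed against the sample consensus; variants at or above
the somatic threshold (0.01 by default) are treated as inherited
heteroplasmy / homoplasmy and removed by :func:`threshold_somatic`.
Between-run batch effects are corrected linearly (additive by default) so
that matched means agree across sequencing runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignmentSet
from .reference import RegionAnnotation, revcomp_codes

SOMATIC_THRESHOLD = 0.01
_BASES = "ACGT"


@dataclass
class SNVCallParams:
    """CLC-style quality filters for a variant observation."""

    q_central: int = 33  # strictly greater than
    q_window: int = 30  # window mean strictly greater than
    radius: int = 5
    max_other_mismatches: int = 2


@dataclass
class SNVTable:
    """Per-position variant allele table plus coverage bookkeeping.

    ``table`` rows: pos (1-based consensus/CRS), ref, alt, count, depth,
    frequency.  ``depth`` is the per-position effective (post-filter) depth
    over all four alleles.
    """

    table: pd.DataFrame
    depth: np.ndarray
    raw_coverage: float
    effective_coverage: float

    @property
    def coverage_reduction(self) -> float:
        """Fraction of raw aligned coverage removed by the quality filters."""
        if self.raw_coverage == 0:
            return 0.0
        return 1.0 - self.effective_coverage / self.raw_coverage


def _window_bounds(rl: int, radius: int) -> tuple[np.ndarray, np.ndarray]:
    j = np.arange(rl)
    return np.maximum(j - radius, 0), np.minimum(j + radius + 1, rl)


def call_snvs(
    aln: AlignmentSet,
    seqs: np.ndarray,
    quals: np.ndarray,
    consensus_codes: np.ndarray,
    exclude: np.ndarray | None = None,
    params: SNVCallParams | None = None,
    chunk: int = 100_000,
) -> SNVTable:
    """Build the per-position four-allele frequency table.

    ``aln`` is the high-stringency pass against the consensus; ``exclude``
    marks reads (e.g. members of broken pairs) that must not contribute.
    """
    params = params or SNVCallParams()
    L = len(consensus_codes)
    n, rl = seqs.shape
    counts = np.zeros(4 * L, dtype=np.int64)
    raw_bases = 0
    eff_bases = 0

    use = aln.accepted.copy()
    if exclude is not None:
        use &= ~np.asarray(exclude, dtype=bool)
    sel = np.flatnonzero(use)
    lo_b, hi_b = _window_bounds(rl, params.radius)
    arange_rl = np.arange(rl, dtype=np.int32)

    def winsum(x, dtype):
        s = np.zeros((len(x), rl + 1), dtype=dtype)
        np.cumsum(x, axis=1, out=s[:, 1:])
        return s[:, hi_b] - s[:, lo_b]

    win_width = (hi_b - lo_b).astype(np.int16)[None, :]

    def process(codes, q, aligned, pos0):
        nonlocal raw_bases, eff_bases, counts
        cons = consensus_codes[pos0]
        full = aligned is None
        if full:
            aligned = np.ones_like(codes, dtype=bool)
        mismatch = aligned & ((codes != cons) | (codes >= 4))
        q = q.astype(np.float32)
        wq = winsum(q if full else np.where(aligned, q, np.float32(0)), np.float32)
        wn = win_width if full else winsum(aligned, np.int16)
        wm = winsum(mismatch, np.int16)
        central_ok = q > params.q_central
        window_ok = wq > np.float32(params.q_window) * wn
        other_ok = (wm - mismatch) <= params.max_other_mismatches
        passing = aligned & central_ok & window_ok & other_ok & (codes < 4)
        raw_bases += int(aligned.sum())
        eff_bases += int(passing.sum())
        flat = (pos0.astype(np.int64) * 4 + np.minimum(codes, 3))[passing]
        counts += np.bincount(flat.ravel(), minlength=4 * L)

    full = sel[(aln.read_start[sel] == 0) & (aln.length[sel] == rl)]
    part = sel[(aln.read_start[sel] != 0) | (aln.length[sel] != rl)]
    for beg in range(0, len(full), chunk):
        idx = full[beg : beg + chunk]
        for st in (0, 1):
            ids = idx[aln.strand[idx] == st]
            if not len(ids):
                continue
            codes = seqs[ids] if st == 0 else revcomp_codes(seqs[ids])
            q = quals[ids] if st == 0 else quals[ids][:, ::-1]
            pos0 = (
                aln.ref_start[ids].astype(np.int64)[:, None] + arange_rl[None, :]
            ) % L
            process(codes, q, None, pos0)
    if len(part):
        idx = part
        strand = aln.strand[idx]
        codes = np.where(strand[:, None] == 0, seqs[idx], revcomp_codes(seqs[idx]))
        q = np.where(strand[:, None] == 0, quals[idx], quals[idx][:, ::-1])
        rs = aln.read_start[idx][:, None]
        ln = aln.length[idx][:, None]
        aligned = (arange_rl[None, :] >= rs) & (arange_rl[None, :] < rs + ln)
        pos0 = (
            aln.ref_start[idx].astype(np.int64)[:, None] + (arange_rl[None, :] - rs)
        ) % L
        process(codes, q, aligned, pos0)

    counts = counts.reshape(L, 4)
    depth = counts.sum(1)
    rows = []
    pos_idx, allele_idx = np.nonzero(counts)
    for p, a in zip(pos_idx, allele_idx):
        if a == consensus_codes[p] or depth[p] == 0:
            continue
        rows.append(
            {
                "pos": int(p) + 1,
                "ref": _BASES[min(int(consensus_codes[p]), 3)],
                "alt": _BASES[a],
                "count": int(counts[p, a]),
                "depth": int(depth[p]),
                "frequency": counts[p, a] / depth[p],
            }
        )
    table = pd.DataFrame(
        rows, columns=["pos", "ref", "alt", "count", "depth", "frequency"]
    )
    return SNVTable(
        table=table,
        depth=depth,
        raw_coverage=raw_bases / L,
        effective_coverage=eff_bases / L,
    )


def threshold_somatic(
    table: pd.DataFrame, threshold: float = SOMATIC_THRESHOLD
) -> pd.DataFrame:
    """Keep sub-threshold (somatic) variants: frequency strictly < threshold."""
    return table[table["frequency"] < threshold].reset_index(drop=True)


def add_annotations(table: pd.DataFrame, annot: RegionAnnotation) -> pd.DataFrame:
    """Attach region, gene class and base-change columns."""
    table = table.copy()
    if not len(table):
        table["region"] = pd.Series(dtype=object)
        table["gene_class"] = pd.Series(dtype=object)
        table["change"] = pd.Series(dtype=object)
        table["transition"] = pd.Series(dtype=bool)
        return table
    pos = table["pos"].to_numpy()
    table["region"] = np.where(annot._is_control[pos], "control", "coding")
    table["gene_class"] = annot._gene_class[pos]
    table["change"] = table["ref"] + ">" + table["alt"]
    transitions = {"A>G", "G>A", "C>T", "T>C"}
    table["transition"] = table["change"].isin(transitions)
    return table


@dataclass
class RunNormalization:
    """Linear between-run correction of SNV frequencies."""

    mode: str
    multiplicative: bool
    offsets: pd.DataFrame  # columns: run, [change,] offset / factor


def normalize_runs(
    tables: dict[str, pd.DataFrame],
    runs: dict[str, str],
    mode: str = "global_mean",
    multiplicative: bool = False,
) -> tuple[dict[str, pd.DataFrame], RunNormalization]:
    """Equalise mean SNV frequencies across sequencing runs.

    ``mode="global_mean"`` applies one scalar per run computed from all
    variant rows; ``mode="per_base_change"`` computes one offset per base
    change from coding-region rows (tables must carry ``change`` and
    ``region`` columns) and applies it to all rows of that change.  The
    correction is additive by default ("correcting linearly"); a
    multiplicative variant is available.  With a single run the transform
    is the identity.
    """
    if mode not in ("global_mean", "per_base_change"):
        raise ValueError(f"unknown mode {mode!r}")
    run_of = dict(runs)
    all_runs = sorted(set(run_of[s] for s in tables))
    frames = []
    for s, df in tables.items():
        d = df.copy()
        d["_sample"] = s
        d["_run"] = run_of[s]
        frames.append(d)
    pooled = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    if len(all_runs) < 2 or not len(pooled):
        offsets = pd.DataFrame({"run": all_runs, "offset": 0.0})
        return {s: df.copy() for s, df in tables.items()}, RunNormalization(
            mode, multiplicative, offsets
        )

    out = {s: df.copy() for s, df in tables.items()}
    records = []
    if mode == "global_mean":
        target = pooled["frequency"].mean()
        for run in all_runs:
            rows = pooled[pooled["_run"] == run]
            run_mean = rows["frequency"].mean() if len(rows) else target
            adj = target - run_mean if not multiplicative else (
                target / run_mean if run_mean > 0 else 1.0
            )
            records.append({"run": run, "offset": adj})
            for s in tables:
                if run_of[s] == run:
                    f = out[s]["frequency"]
                    out[s]["frequency"] = (
                        np.maximum(f + adj, 0.0) if not multiplicative else f * adj
                    )
    else:
        if "change" not in pooled.columns or "region" not in pooled.columns:
            raise ValueError("per_base_change mode needs annotated tables")
        coding = pooled[pooled["region"] == "coding"]
        for change, grp in coding.groupby("change"):
            target = grp["frequency"].mean()
            for run in all_runs:
                rows = grp[grp["_run"] == run]
                run_mean = rows["frequency"].mean() if len(rows) else target
                adj = target - run_mean if not multiplicative else (
                    target / run_mean if run_mean > 0 else 1.0
                )
                records.append({"run": run, "change": change, "offset": adj})
                for s in tables:
                    if run_of[s] != run:
                        continue
                    mask = out[s]["change"] == change
                    f = out[s].loc[mask, "frequency"]
                    out[s].loc[mask, "frequency"] = (
                        np.maximum(f + adj, 0.0) if not multiplicative else f * adj
                    )
    return out, RunNormalization(mode, multiplicative, pd.DataFrame(records))
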