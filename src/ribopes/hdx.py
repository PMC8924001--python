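"""HDX-MS differential deuterium-uptake analysis.

Peptide-level deuterium uptake is the centroid-mass increase over the
undeuterated (t = 0) measurement, without back-exchange correction.  The
first two residues of every peptide are assumed unable to retain deuterium
and prolines carry no exchangeable amide hydrogen, so a peptide's maximum
exchangeable count is ``length - 2 - (# prolines at positions >= 3)``.
Differential uptake between the ligand-bound and apo states is thresholded
at +/-0.5 Da (the residual-plot significance criterion); per-residue maps
average the peptide-level differences over covering peptides and then apply
a moving-average smoothing ("heavy smoothing", quantified here as a
5-residue window), leaving prolines and uncovered residues blank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_DELTA_THRESHOLD = 0.5  # Da
DEFAULT_RECOVERY = 0.8
DEFAULT_SMOOTHING_WINDOW = 5
RT_MATCH_WINDOW_MIN = 0.5

STATES = ("apo", "ligand")


def max_exchangeable(sequence: str) -> int:
    """Number of backbone amides of a peptide that can retain deuterium."""
    seq = sequence.upper()
    if len(seq) < 3:
        raise ValueError("peptide too short to hold deuteration (< 3 residues)")
    return len(seq) - 2 - seq[2:].count("P")


def read_state_table(path_or_df, confidence_filter: Sequence[str] = ("high", "medium")) -> pd.DataFrame:
    """Ingest an HDX state-data table (CSV path or DataFrame).

    Required columns: peptide_start, peptide_end, sequence, state, exposure_s,
    centroid_mass_da; optional: charge, confidence, retention_time_min.
    Low-confidence rows are dropped; duplicate entries of the same peptide /
    state / exposure whose retention times agree within +/-0.5 min are
    collapsed by averaging their centroids.
    """
    df = pd.read_csv(path_or_df) if not isinstance(path_or_df, pd.DataFrame) else path_or_df.copy()
    required = {"peptide_start", "peptide_end", "sequence", "state",
                "exposure_s", "centroid_mass_da"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"state table missing columns: {sorted(missing)}")
    if "confidence" in df.columns and confidence_filter is not None:
        df = df[df["confidence"].isin(confidence_filter)]

    keys = ["peptide_start", "peptide_end", "sequence", "state", "exposure_s"]
    if "charge" in df.columns:
        keys.append("charge")
    if "retention_time_min" in df.columns:
        collapsed = []
        for _, grp in df.groupby(keys, sort=False):
            if len(grp) == 1:
                collapsed.append(grp)
                continue
            rt = grp["retention_time_min"].to_numpy(float)
            if np.nanmax(rt) - np.nanmin(rt) <= RT_MATCH_WINDOW_MIN:
                row = grp.iloc[[0]].copy()
                row["centroid_mass_da"] = grp["centroid_mass_da"].mean()
                row["retention_time_min"] = grp["retention_time_min"].mean()
                collapsed.append(row)
            else:  # retention times disagree: keep separate observations
                collapsed.append(grp)
        df = pd.concat(collapsed, ignore_index=True)
    else:
        df = df.groupby(keys, as_index=False).agg(
            {c: "mean" if np.issubdtype(df[c].dtype, np.number) else "first"
             for c in df.columns if c not in keys}
        )
    df["peptide_id"] = (df["peptide_start"].astype(str) + "-"
                        + df["peptide_end"].astype(str) + ":" + df["sequence"])
    if "charge" in df.columns:
        df["peptide_id"] = df["peptide_id"] + "/+" + df["charge"].astype(str)
    # distinct retention-time species of the same peptide/charge stay separate
    if "retention_time_min" in df.columns:
        df = df.sort_values(["peptide_id", "retention_time_min"], kind="stable")
        rt_species = []
        last = {}
        for pid, rt in zip(df["peptide_id"], df["retention_time_min"]):
            prev = last.get(pid)
            if prev is None:
                last[pid] = (rt, 0)
            elif abs(rt - prev[0]) > RT_MATCH_WINDOW_MIN:
                last[pid] = (rt, prev[1] + 1)
            else:
                last[pid] = (rt, prev[1])
            rt_species.append(last[pid][1])
        df = df.assign(rt_species=rt_species)
        multi = df.groupby("peptide_id")["rt_species"].transform("max") > 0
        df.loc[multi, "peptide_id"] = (df.loc[multi, "peptide_id"] + "#"
                                       + df.loc[multi, "rt_species"].astype(str))
        df = df.drop(columns="rt_species")
    return df.reset_index(drop=True)


def compute_uptake(state_table: pd.DataFrame) -> pd.DataFrame:
    """Deuterium uptake D(t) = centroid(t) - centroid(0) per peptide and state.

    Peptides lacking a t = 0 centroid in a state are dropped with a logged
    reason.  Negative uptake values are retained and flagged as below-zero
    artifacts.  No back-exchange correction is applied.
    """
    df = state_table if "peptide_id" in state_table.columns else read_state_table(state_table)
    out = []
    for (pid, state), grp in df.groupby(["peptide_id", "state"], sort=True):
        grp = grp.sort_values("exposure_s")
        t0 = grp[grp["exposure_s"] == 0]
        if t0.empty:
            logger.info("dropping %s/%s: no t=0 centroid", pid, state)
            continue
        base = float(t0["centroid_mass_da"].iloc[0])
        g = grp.copy()
        g["uptake_da"] = g["centroid_mass_da"].astype(float) - base
        g["below_zero"] = g["uptake_da"] < 0
        out.append(g)
    if not out:
        return pd.DataFrame(columns=list(df.columns) + ["uptake_da", "below_zero"])
    return pd.concat(out, ignore_index=True)


def normalize_uptake(uptake_da, sequence: str,
                     d2o_fraction: float = 1.0,
                     recovery: float = DEFAULT_RECOVERY):
    """Uptake as a fraction of the peptide's maximum, normalized to 100% D2O.

    fraction = D / (max_exchangeable * d2o_fraction * recovery); NaN when the
    peptide has no exchangeable amides.
    """
    if not 0 < recovery <= 1:
        raise ValueError("recovery must be in (0, 1]")
    if not 0 < d2o_fraction <= 1:
        raise ValueError("d2o_fraction must be in (0, 1]")
    mx = max_exchangeable(sequence)
    if mx == 0:
        return np.nan if np.isscalar(uptake_da) else np.full(len(uptake_da), np.nan)
    return np.asarray(uptake_da, dtype=float) / (mx * d2o_fraction * recovery) \
        if not np.isscalar(uptake_da) else float(uptake_da) / (mx * d2o_fraction * recovery)


def differential_uptake(
    uptake: pd.DataFrame,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    states: tuple[str, str] = STATES,
) -> pd.DataFrame:
    """Per-peptide uptake difference (ligand - apo) per timepoint and for max uptake.

    Rows with exposure_s == 'max' carry the difference of each state's
    maximum uptake across timepoints.  significance is 'protected' when
    delta <= -threshold, 'exposed' when delta >= +threshold, else 'ns'.
    """
    apo_label, ligand_label = states
    rows = []
    for pid, grp in uptake.groupby("peptide_id", sort=True):
        apo = grp[grp["state"] == apo_label].groupby("exposure_s")["uptake_da"].mean()
        lig = grp[grp["state"] == ligand_label].groupby("exposure_s")["uptake_da"].mean()
        if apo.empty or lig.empty:
            continue
        shared = apo.index.intersection(lig.index)
        if len(shared) < len(apo.index.union(lig.index)):
            logger.warning("%s: unmatched timepoint grids, intersecting", pid)
        meta = grp.iloc[0]
        for t in sorted(shared):
            delta = float(lig.loc[t] - apo.loc[t])
            rows.append({"peptide_id": pid, "peptide_start": meta["peptide_start"],
                         "peptide_end": meta["peptide_end"], "sequence": meta["sequence"],
                         "exposure_s": t, "delta_da": delta,
                         "significance": _call(delta, delta_threshold)})
        dmax = float(lig.loc[list(shared)].max() - apo.loc[list(shared)].max())
        rows.append({"peptide_id": pid, "peptide_start": meta["peptide_start"],
                     "peptide_end": meta["peptide_end"], "sequence": meta["sequence"],
                     "exposure_s": "max", "delta_da": dmax,
                     "significance": _call(dmax, delta_threshold)})
    return pd.DataFrame(rows)


def _call(delta: float, threshold: float) -> str:
    if delta <= -threshold:
        return "protected"
    if delta >= threshold:
        return "exposed"
    return "ns"


@dataclass
class ResidueDeltaMap:
    """Per-residue differential-uptake map (rows residues, columns timepoints + 'max')."""

    values: pd.DataFrame       # smoothed per-residue delta, NaN where uncovered/proline
    raw_values: pd.DataFrame   # pre-smoothing per-residue means
    coverage: np.ndarray       # covering-peptide count per residue (competent coverage)
    calls: pd.DataFrame        # protected/exposed/ns/uncovered per residue x column


def residue_delta_map(
    peptide_deltas: pd.DataFrame,
    protein_sequence: str,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> ResidueDeltaMap:
    """Aggregate per-peptide uptake differences to residue resolution.

    Each exchange-competent residue (position >= start+2 of a covering
    peptide, non-proline) receives the unweighted mean of delta over covering
    peptides, then a centered moving average of odd width ``smoothing_window``
    is applied along each contiguous covered run (window 1 disables).
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be odd and >= 1")
    protein = protein_sequence.upper()
    n = len(protein)
    columns = sorted({t for t in peptide_deltas["exposure_s"] if t != "max"}) + ["max"]

    sums = {c: np.zeros(n) for c in columns}
    counts = {c: np.zeros(n, dtype=np.int64) for c in columns}
    cov = np.zeros(n, dtype=np.int64)
    seen_for_cov = set()
    for _, row in peptide_deltas.iterrows():
        start, end = int(row["peptide_start"]), int(row["peptide_end"])
        if start < 1 or end > n:
            raise ValueError(f"peptide {start}-{end} outside protein of length {n}")
        competent = [r for r in range(start + 2, end + 1) if protein[r - 1] != "P"]
        if not competent:
            continue
        col = row["exposure_s"]
        idx = np.asarray(competent) - 1
        sums[col][idx] += float(row["delta_da"])
        counts[col][idx] += 1
        if row["peptide_id"] not in seen_for_cov:
            seen_for_cov.add(row["peptide_id"])
            cov[idx] += 1

    raw = {}
    smooth = {}
    for c in columns:
        with np.errstate(invalid="ignore"):
            mean = np.where(counts[c] > 0, sums[c] / np.maximum(counts[c], 1), np.nan)
        raw[c] = mean
        smooth[c] = _smooth_runs(mean, smoothing_window)

    residues = np.arange(1, n + 1)
    raw_df = pd.DataFrame(raw, index=residues)
    smooth_df = pd.DataFrame(smooth, index=residues)
    raw_df.index.name = smooth_df.index.name = "residue"

    calls = pd.DataFrame("uncovered", index=residues, columns=columns)
    for c in columns:
        vals = smooth_df[c].to_numpy()
        covered = ~np.isnan(vals)
        calls.loc[covered, c] = [_call(v, delta_threshold) for v in vals[covered]]
    calls.index.name = "residue"
    return ResidueDeltaMap(values=smooth_df, raw_values=raw_df, coverage=cov, calls=calls)


def _smooth_runs(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average within each contiguous non-NaN run."""
    if window == 1:
        return values.copy()
    half = window // 2
    out = np.full_like(values, np.nan)
    n = len(values)
    isnum = ~np.isnan(values)
    i = 0
    while i < n:
        if not isnum[i]:
            i += 1
            continue
        j = i
        while j < n and isnum[j]:
            j += 1
        run = values[i:j]
        sm = np.array([
            run[max(0, k - half): k + half + 1].mean() for k in range(len(run))
        ])
        out[i:j] = sm
        i = j
    return out


@dataclass(frozen=True)
class HdxQcStats:
    peptide_count: int
    mean_length: float
    sd_length: float
    sequence_coverage: float  # percent of protein residues covered
    redundancy: float         # mean covering peptides per covered residue

    def as_dict(self) -> dict:
        return {
            "peptide_count": self.peptide_count,
            "mean_length": self.mean_length,
            "sd_length": self.sd_length,
            "sequence_coverage": self.sequence_coverage,
            "redundancy": self.redundancy,
        }


def hdx_qc(peptides: pd.DataFrame, protein_length: int) -> HdxQcStats:
    """Coverage/redundancy/length statistics of a peptide map.

    ``peptides`` needs one row per peptide with peptide_start / peptide_end
    (1-based inclusive); every row counts as one peptide, so repeated entries
    (e.g. charge states) raise the redundancy, as in instrument exports.
    """
    uniq = peptides
    if uniq.empty:
        raise ValueError("empty peptide list")
    depth = np.zeros(protein_length, dtype=np.int64)
    lengths = []
    for _, row in uniq.iterrows():
        s, e = int(row["peptide_start"]), int(row["peptide_end"])
        depth[s - 1 : e] += 1
        lengths.append(e - s + 1)
    covered = depth > 0
    coverage = 100.0 * covered.sum() / protein_length
    redundancy = float(depth[covered].mean()) if covered.any() else 0.0
    lengths = np.asarray(lengths, dtype=float)
    return HdxQcStats(
        peptide_count=len(uniq),
        mean_length=float(lengths.mean()),
        sd_length=float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        sequence_coverage=coverage,
        redundancy=redundancy,
    )
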