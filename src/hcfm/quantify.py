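"""Ecological summaries: abundance normalization and covariate correlation.

Object counts per sample and taxon are converted to concentrations in
counts per liter of seawater: counts from technical replicates of the
same sample are summed and their imaged volumes summed *before* division.
Relationships with environmental covariates (e.g. phosphate
concentration) are assessed with Spearman rank correlation over the
samples that contain the taxon; samples with a zero count of the taxon
are excluded from that taxon's analysis.  A least-squares line is
reported for display alongside the rank correlation.

P-values: exact (permutation enumeration of rank assignments) for
n <= 9 samples, the large-sample t approximation otherwise; tied ranks
use the average-rank convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

EXACT_P_MAX_N = 9


@dataclass
class AbundanceTable:
    """Per (sample, taxon) counts and concentrations in counts per liter."""

    frame: pd.DataFrame  # columns: sample, taxon, count, volume_l, per_liter

    def concentration(self, sample: str, taxon: str) -> float:
        sel = self.frame[(self.frame["sample"] == sample) & (self.frame["taxon"] == taxon)]
        if sel.empty:
            raise KeyError(f"no abundance entry for ({sample!r}, {taxon!r})")
        return float(sel["per_liter"].iloc[0])

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def normalize_counts(
    counts: pd.DataFrame,
    volumes_l: Mapping[str, float],
    replicate_map: Mapping[str, str] | None = None,
) -> AbundanceTable:
    """Counts per liter of seawater, pooling technical replicates.

    ``counts`` has columns (sample, taxon, count); ``volumes_l`` maps each
    sample (replicate) to its imaged seawater volume in liters.
    ``replicate_map`` maps replicate names to a pooled sample name;
    replicate counts and volumes are summed before division.  Samples
    with no volume entry are excluded with a warning.  Zero counts are
    valid (concentration 0).
    """
    df = counts.copy()
    missing = sorted(set(df["sample"]) - set(volumes_l))
    if missing:
        warnings.warn(f"samples excluded for missing volume: {missing}", stacklevel=2)
        df = df[~df["sample"].isin(missing)]
    bad = {s: v for s, v in volumes_l.items() if v <= 0}
    if bad:
        raise ValueError(f"volumes must be positive liters: {bad}")
    replicate_map = replicate_map or {}
    df["pooled"] = df["sample"].map(lambda s: replicate_map.get(s, s))
    vol = pd.Series(dict(volumes_l), name="volume_l")
    vol = vol[~vol.index.isin(missing)].to_frame()
    vol["pooled"] = [replicate_map.get(s, s) for s in vol.index]
    pooled_vol = vol.groupby("pooled")["volume_l"].sum()
    agg = df.groupby(["pooled", "taxon"], as_index=False)["count"].sum()
    agg = agg.rename(columns={"pooled": "sample"})
    agg["volume_l"] = agg["sample"].map(pooled_vol)
    agg["per_liter"] = agg["count"] / agg["volume_l"]
    return AbundanceTable(frame=agg)


@dataclass
class CorrelationResult:
    """Spearman rank correlation of one taxon with one covariate."""

    taxon: str
    rho: float
    p_value: float
    n: int
    slope: float  # least-squares display line
    intercept: float


def _ranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho as the Pearson correlation of average ranks."""
    rx, ry = _ranks(np.asarray(x, float)), _ranks(np.asarray(y, float))
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _exact_p(x: np.ndarray, y: np.ndarray, observed: float) -> float:
    """Two-sided exact p by enumerating permutations of one rank vector."""
    rx, ry = _ranks(x), _ranks(y)
    rx = rx - rx.mean()
    denom = np.sqrt((rx**2).sum())
    rx = rx / denom
    null = []
    for perm in permutations(ry):
        r = np.asarray(perm, float)
        r = r - r.mean()
        d = np.sqrt((r**2).sum())
        null.append(float(rx @ (r / d)))
    null = np.abs(np.asarray(null))
    return float((null >= abs(observed) - 1e-12).mean())


def correlate_with_covariate(
    table: AbundanceTable,
    covariate: Mapping[str, float],
    taxon: str,
) -> CorrelationResult:
    """Spearman correlation of a taxon's concentration with a covariate.

    Only samples containing the taxon (count > 0) enter; fewer than 3
    usable samples is an error.
    """
    sel = table.frame[(table.frame["taxon"] == taxon) & (table.frame["count"] > 0)]
    sel = sel[sel["sample"].isin(covariate)]
    n = len(sel)
    if n < 3:
        raise ValueError(
            f"taxon {taxon!r}: only {n} samples with non-zero counts and a "
            "covariate value (need >= 3)"
        )
    x = np.array([covariate[s] for s in sel["sample"]], dtype=float)
    y = sel["per_liter"].to_numpy(dtype=float)
    rho = spearman_rho(x, y)
    if np.isnan(rho):
        p = float("nan")
    elif n <= EXACT_P_MAX_N:
        p = _exact_p(x, y, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationResult(
        taxon=taxon, rho=rho, p_value=p, n=n,
        slope=float(slope), intercept=float(intercept),
    )


def correlation_table(
    table: AbundanceTable, covariate: Mapping[str, float], taxa: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for taxon in taxa:
        try:
            r = correlate_with_covariate(table, covariate, taxon)
        except ValueError:
            continue
        rows.append(
            {"taxon": r.taxon, "rho": r.rho, "p_value": r.p_value, "n": r.n,
             "slope": r.slope, "intercept": r.intercept}
        )
    return pd.DataFrame(rows, columns=["taxon", "rho", "p_value", "n", "slope", "intercept"])


def is_live_cell(feature_row: Mapping[str, float]) -> bool:
    """Predicate for cells with preserved organellar content.

    Operationalized as: at least one DNA sub-object and non-zero membrane
    biovolume.
    """
    return (
        feature_row["dna.subobject_count"] >= 1
        and feature_row["membranes.biovolume_um3"] > 0
    )
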