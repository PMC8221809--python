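"""TMT reporter-intensity quantification chain.

PSM filtering (co-isolation < 0.5, mean reporter S/N > 10) and summation to
protein x channel intensities; channel loading normalization (each channel
sum divided by the mean of all channel sums); seeded low-abundance
resampling imputation; per-kit log2 centering; equal-variance two-sample
t-tests with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PlexDesign",
    "ProteomicsError",
    "filter_aggregate_psms",
    "loading_normalize",
    "impute_low_abundance",
    "log2_center",
    "bh_qvalues",
    "differential_expression",
    "annotation_subset",
    "read_psm_table",
    "read_design",
    "read_annotation",
]

META_COLS = ("protein", "peptide", "psm_id", "coiso", "sn")


class ProteomicsError(ValueError):
    pass


@dataclass
class PlexDesign:
    """Channel -> (kit, sample, group, is_bridge) mapping."""

    table: pd.DataFrame  # columns: channel, kit, sample, group, is_bridge

    def __post_init__(self) -> None:
        required = {"channel", "kit", "sample"}
        missing = required - set(self.table.columns)
        if missing:
            raise ProteomicsError(f"design table missing columns: {sorted(missing)}")
        if "is_bridge" not in self.table.columns:
            self.table = self.table.assign(is_bridge=False)
        sizes = self.table.groupby("kit").size()
        if (sizes < 2).any():
            raise ProteomicsError("each kit needs >= 2 channels")
        bridges = self.table[self.table["is_bridge"].astype(bool)]
        if len(bridges):
            kits_with_bridge = set(bridges["kit"])
            if kits_with_bridge != set(self.table["kit"]):
                raise ProteomicsError("declared bridge sample must be present in every kit")

    @property
    def channels(self) -> list[str]:
        return list(self.table["channel"])

    def kit_channels(self) -> dict[str, list[str]]:
        return {
            kit: list(sub["channel"]) for kit, sub in self.table.groupby("kit", sort=False)
        }

    def groups(self) -> dict[str, str]:
        if "group" not in self.table.columns:
            raise ProteomicsError("design table has no 'group' column")
        return dict(zip(self.table["channel"], self.table["group"]))


def filter_aggregate_psms(
    table: pd.DataFrame,
    coiso_max: float = 0.5,
    sn_min: float = 10.0,
    channel_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sum reporter intensities of passing PSMs to protein x channel.

    Keeps PSMs with co-isolation interference strictly below ``coiso_max``
    and mean reporter S/N strictly above ``sn_min``.  Proteins with no
    passing PSMs are absent from the output.
    """
    if not 0 <= coiso_max <= 1:
        raise ProteomicsError("coiso_max must be in [0, 1]")
    if sn_min < 0:
        raise ProteomicsError("sn_min must be >= 0")
    cols = list(channel_cols) if channel_cols is not None else [
        c for c in table.columns if c not in META_COLS
    ]
    if table.empty:
        return pd.DataFrame(columns=cols)
    passing = table[(table["coiso"] < coiso_max) & (table["sn"] > sn_min)]
    return passing.groupby("protein")[cols].sum(min_count=1)


def loading_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each channel by its loading factor (channel sum / mean of sums)."""
    sums = matrix.sum(axis=0, skipna=True)
    zero = sums[sums <= 0]
    if len(zero):
        raise ProteomicsError(f"zero-sum channel(s): {list(zero.index)}")
    factors = sums / sums.mean()
    return matrix / factors, factors


def impute_low_abundance(
    matrix: pd.DataFrame, quantile: float = 0.05, seed: int | None = None
) -> pd.DataFrame:
    """Replace missing entries with draws from the channel's low tail.

    Missing entries are resampled (seeded) from the observed values at or
    below the channel's ``quantile`` cutoff; observed entries are untouched.
    This is a declared interpretation of "low abundance resampling".
    """
    if not 0 < quantile <= 1:
        raise ProteomicsError("quantile must be in (0, 1]")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    for col in out.columns:
        vals = out[col]
        missing = vals.isna()
        if not missing.any():
            continue
        observed = vals.dropna().to_numpy()
        if observed.size == 0:
            raise ProteomicsError(f"channel {col!r} is fully missing; cannot impute")
        cutoff = np.quantile(observed, quantile)
        pool = observed[observed <= cutoff]
        out.loc[missing, col] = rng.choice(pool, size=int(missing.sum()), replace=True)
    return out


def log2_center(matrix: pd.DataFrame, design: PlexDesign) -> pd.DataFrame:
    """log2-transform and center each protein on its per-kit mean.

    Kits are centered independently and then combined, so per-kit global
    scale differences cancel.
    """
    if (matrix <= 0).any().any() or matrix.isna().any().any():
        raise ProteomicsError(
            "matrix has missing or non-positive intensities; impute first"
        )
    pieces = []
    for kit, cols in design.kit_channels().items():
        cols = [c for c in cols if c in matrix.columns]
        if not cols:
            continue
        logs = np.log2(matrix[cols])
        pieces.append(logs.sub(logs.mean(axis=1), axis=0))
    return pd.concat(pieces, axis=1)


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    norm: pd.DataFrame,
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    q_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Per-protein equal-variance t-test (a vs b) with BH FDR.

    Returns mean_a, mean_b, the log2 difference (a - b), t, p, q and a
    significance flag at ``q_cutoff`` (configurable, not hard-coded).
    """
    cols_a = [c for c in norm.columns if groups.get(c) == group_a]
    cols_b = [c for c in norm.columns if groups.get(c) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ProteomicsError(
            f"each group needs >= 2 channels (got {len(cols_a)} vs {len(cols_b)})"
        )
    a = norm[cols_a].to_numpy(float)
    b = norm[cols_b].to_numpy(float)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_qvalues(p)
    return pd.DataFrame(
        {
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "log2_diff": a.mean(axis=1) - b.mean(axis=1),
            "t": t,
            "p": p,
            "q": q,
            "significant": q < q_cutoff,
        },
        index=norm.index,
    )


def annotation_subset(
    matrix: pd.DataFrame, accessions: Sequence[str]
) -> tuple[pd.DataFrame, float]:
    """Restrict rows to an annotation list; returns (subset, fraction kept)."""
    accs = set(accessions)
    if not accs:
        raise ProteomicsError("annotation list must be non-empty")
    keep = matrix.index.isin(accs)
    if not keep.any():
        warnings.warn("no overlap between matrix and annotation list", stacklevel=2)
    fraction = float(keep.sum()) / len(matrix) if len(matrix) else 0.0
    return matrix.loc[keep], fraction


# ---------------------------------------------------------------------------
# IO


def read_psm_table(path) -> pd.DataFrame:
    """TSV with columns protein,peptide,psm_id,coiso,sn,<channel...>."""
    return pd.read_csv(path, sep="\t")


def read_design(path) -> PlexDesign:
    """TSV with columns channel,kit,sample[,group,is_bridge]."""
    return PlexDesign(pd.read_csv(path, sep="\t"))


def read_annotation(path) -> list[str]:
    """One accession per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
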