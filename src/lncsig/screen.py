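"""Downstream marker screening statistics.

Group comparisons with star categories, knock-down (KD) screen calls on
drop-zero k-mer means, subcellular compartment profiles, positive-cell
labelling and marker calling in single-cell matrices, and ddCt relative
quantification for qPCR validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def star_category(p: float) -> str:
    """Significance stars: ns > 0.05 >= * > 0.01 >= ** > 0.001 >= *** > 0.0001 >= ****."""
    if np.isnan(p):
        return "ns"
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    if p > 0.0001:
        return "***"
    return "****"


def group_t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, str, int]:
    """Two-sample t test (Welch by default) with star category.

    Returns (p, star, direction) with direction = sign(mean_b - mean_a).
    Degenerate input (all values identical in both groups) gives p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    direction = int(np.sign(b.mean() - a.mean()))
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
        if np.isnan(p):
            p = 1.0
    return p, star_category(p), direction


def kd_screen(
    sample_means: Mapping[str, float],
    control_samples: Sequence[str],
    kd_groups: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-KD t test of control vs knock-down drop-zero sample means.

    ``sample_means`` holds one drop-zero-averaged k-mer abundance per
    sample. Singleton KD groups are flagged and excluded. Output is
    sorted by p.
    """
    controls = [sample_means[s] for s in control_samples]
    if len(controls) < 2:
        raise ValueError("need >= 2 control samples")
    rows = []
    for kd, samples in kd_groups.items():
        if len(samples) < 2:
            rows.append(
                {"kd": kd, "p": np.nan, "star": "ns", "direction": 0, "excluded": True}
            )
            continue
        vals = [sample_means[s] for s in samples]
        p, star, direction = group_t_test(controls, vals)
        rows.append({"kd": kd, "p": p, "star": star, "direction": direction, "excluded": False})
    df = pd.DataFrame(rows)
    return df.sort_values(["excluded", "p"], na_position="last").reset_index(drop=True)


def compartment_profile(abundances: Mapping[str, float]) -> tuple[dict[str, float], str]:
    """Fractional enrichment across subcellular fractions.

    Returns (shares summing to 1, dominant fraction). All-zero input is
    undefined and raises.
    """
    total = sum(abundances.values())
    if total <= 0:
        raise ValueError("all fractions zero: profile undefined")
    shares = {name: v / total for name, v in abundances.items()}
    dominant = max(shares, key=lambda name: (shares[name], name))
    return shares, dominant


@dataclass
class CellLabeling:
    """Positive/negative call per cell for one marker."""

    positive: pd.Series  # bool per cell
    tau: float

    @property
    def n_positive(self) -> int:
        return int(self.positive.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.positive).sum())


def filter_droplets(counts: pd.DataFrame, min_count: int = 10000) -> pd.DataFrame:
    """Keep droplets (rows) with a total count of at least ``min_count``."""
    return counts.loc[counts.sum(axis=1) >= min_count]


def label_cells(scaled_expression: pd.Series, tau: float = 0.1) -> CellLabeling:
    """A cell is positive when its scaled expression is >= tau."""
    return CellLabeling(positive=scaled_expression >= tau, tau=tau)


def marker_differential(
    matrix: pd.DataFrame,
    labeling: CellLabeling,
    min_lfc: float = 0.15,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes differential between marker-positive and -negative cells.

    ``matrix`` is cells x genes (raw or normalised counts). Per gene,
    lfc = mean ln(x+1) in positive cells minus negative cells; genes
    with |lfc| < min_lfc are excluded before testing; p comes from a
    Mann-Whitney rank-sum test, Bonferroni-adjusted over tested genes.
    """
    pos_mask = labeling.positive.reindex(matrix.index)
    if pos_mask.isna().any():
        raise ValueError("labeling does not cover all cells in the matrix")
    pos_mask = pos_mask.astype(bool)
    if pos_mask.sum() == 0 or (~pos_mask).sum() == 0:
        raise ValueError("one label class is empty")
    logm = np.log1p(matrix.values.astype(float))
    lfc = logm[pos_mask.values].mean(axis=0) - logm[~pos_mask.values].mean(axis=0)
    genes = matrix.columns
    tested = np.abs(lfc) >= min_lfc
    rows = []
    n_tests = int(tested.sum())
    for j, gene in enumerate(genes):
        if not tested[j]:
            continue
        x = matrix.values[pos_mask.values, j]
        y = matrix.values[~pos_mask.values, j]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        p_adj = min(1.0, p * n_tests)
        rows.append(
            {
                "gene": gene,
                "lfc": float(lfc[j]),
                "p": p,
                "p_adj": p_adj,
                "direction": int(np.sign(lfc[j])),
                "significant": p_adj <= alpha,
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene", "lfc", "p", "p_adj", "direction", "significant"]
    )
    return df.sort_values("p_adj").reset_index(drop=True) if len(df) else df


@dataclass
class DdctInput:
    """Ct values for target and reference (housekeeping) genes per sample.

    Replicate Ct values are averaged per sample before the arithmetic.
    ``calibrator_samples`` defines the group whose mean dCt anchors RQ = 1.
    """

    target_ct: dict[str, Sequence[float]]
    reference_ct: dict[str, Sequence[float]]
    calibrator_samples: Sequence[str]

    def __post_init__(self) -> None:
        for sample in self.target_ct:
            if sample not in self.reference_ct:
                raise ValueError(f"missing reference Ct for sample {sample!r}")
            for ct in list(self.target_ct[sample]) + list(self.reference_ct[sample]):
                if ct <= 0:
                    raise ValueError(f"non-positive Ct in sample {sample!r}")
        for sample in self.calibrator_samples:
            if sample not in self.target_ct:
                raise ValueError(f"calibrator sample {sample!r} has no Ct values")


def ddct(inp: DdctInput) -> pd.DataFrame:
    """ddCt relative quantification.

    dCt = mean Ct_target - mean Ct_reference per sample;
    ddCt = dCt - mean dCt over the calibrator group; RQ = 2**(-ddCt);
    log induction = -ddCt.
    """
    dct = {
        s: float(np.mean(inp.target_ct[s])) - float(np.mean(inp.reference_ct[s]))
        for s in inp.target_ct
    }
    calibrator_dct = float(np.mean([dct[s] for s in inp.calibrator_samples]))
    rows = []
    for s in sorted(dct):
        ddct_val = dct[s] - calibrator_dct
        rows.append(
            {
                "sample": s,
                "dct": dct[s],
                "ddct": ddct_val,
                "rq": 2.0 ** (-ddct_val),
                "log_induction": -ddct_val,
            }
        )
    return pd.DataFrame(rows)
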