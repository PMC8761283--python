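"""Differential expression, luciferase statistics, and gene cross-referencing.

Significance follows a dual rule throughout: two-sided t-test p < 0.05 AND
|signed fold change| >= 1.5.  Fold changes are signed so magnitudes are
always >= 1: up-regulation is mean(cancer)/mean(normal), down-regulation is
reported as the negated reciprocal (a 25.7-fold drop prints as -25.7); no
value falls strictly between -1 and 1.  Group means get a pseudo-count of 1
before the ratio so genes silent in one group (e.g. TERT in normal bladder)
stay finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import round_half_up


class ExpressionError(ValueError):
    pass


@dataclass
class DEResult:
    gene_id: str
    signed_fold_change: float
    p_value: float
    significant: bool
    testable: bool = True


@dataclass
class LuciferaseArm:
    """Replicate (firefly, Renilla) activity pairs for one construct arm."""
    construct_id: str
    arm: str                        # "wild_type" | "mutant"
    firefly: tuple[float, ...]
    renilla: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.firefly) != len(self.renilla):
            raise ExpressionError(
                f"{self.construct_id}/{self.arm}: unpaired replicates")
        if any(r <= 0 for r in self.renilla):
            raise ExpressionError(
                f"{self.construct_id}/{self.arm}: Renilla activity must be > 0")


def signed_fold(numerator_mean: float, denominator_mean: float,
                pseudocount: float = 1.0) -> float:
    """Signed ratio of group means with magnitudes >= 1.

    Ratios >= 1 are returned as-is (up); ratios < 1 are returned as the
    negated reciprocal (down), matching the convention that a 25.7-fold
    decrease is written -25.7.
    """
    ratio = (numerator_mean + pseudocount) / (denominator_mean + pseudocount)
    return ratio if ratio >= 1.0 else -1.0 / ratio


def two_sample_t(a: Sequence[float], b: Sequence[float],
                 equal_var: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: no within-group variance; equal means are a clean null
        return (0.0, 1.0) if math.isclose(a.mean(), b.mean()) else (math.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def differential_expression(matrix: pd.DataFrame, groups: Mapping[str, str],
                            genes: Iterable[str] | None = None,
                            p_max: float = 0.05, fold_min: float = 1.5,
                            log_transform: bool = True,
                            equal_var: bool = False,
                            pseudocount: float = 1.0) -> list[DEResult]:
    """Per-gene cancer-vs-normal test on an expression matrix.

    ``matrix`` is genes x samples (non-negative values); ``groups`` maps
    sample name to "cancer" or "normal".  The t-test runs on log2(x+1) by
    default (RNA-seq convention); the fold change is the signed ratio of
    raw-scale group means with a pseudo-count.  Genes absent from the
    matrix are reported untestable rather than dropped.
    """
    cancer = [s for s in matrix.columns if groups.get(s) == "cancer"]
    normal = [s for s in matrix.columns if groups.get(s) == "normal"]
    if len(cancer) < 2 or len(normal) < 2:
        raise ExpressionError("need >= 2 samples per group")
    if (matrix[cancer + normal].values < 0).any():
        raise ExpressionError("expression values must be non-negative")
    targets = list(genes) if genes is not None else list(matrix.index)
    results: list[DEResult] = []
    for gene in targets:
        if gene not in matrix.index:
            results.append(DEResult(gene, float("nan"), float("nan"),
                                    False, testable=False))
            continue
        xc = matrix.loc[gene, cancer].to_numpy(dtype=float)
        xn = matrix.loc[gene, normal].to_numpy(dtype=float)
        tc = np.log2(xc + 1) if log_transform else xc
        tn = np.log2(xn + 1) if log_transform else xn
        _, p = two_sample_t(tc, tn, equal_var=equal_var)
        fc = signed_fold(float(xc.mean()), float(xn.mean()), pseudocount)
        results.append(DEResult(gene, fc, p,
                                significant=(p < p_max and abs(fc) >= fold_min)))
    return results


# ---------------------------------------------------------------------------
# luciferase

def normalize_luciferase(arm: LuciferaseArm) -> tuple[list[float], float]:
    """Per-replicate normalized activity E_l = E_f / E_r and the arm mean."""
    el = [f / r for f, r in zip(arm.firefly, arm.renilla)]
    return el, float(np.mean(el))


def test_luciferase(wild_type: LuciferaseArm, mutant: LuciferaseArm,
                    p_max: float = 0.05, fold_min: float = 1.5,
                    equal_var: bool = False) -> dict:
    """Mutant-vs-wild-type comparison of normalized luciferase activity.

    Fold = mean(mutant E_l) / mean(wild-type E_l), signed; significance is
    the dual rule (p < ``p_max`` AND |fold| >= ``fold_min``).  Requires at
    least 3 replicates per arm.
    """
    wt_el, wt_mean = normalize_luciferase(wild_type)
    mut_el, mut_mean = normalize_luciferase(mutant)
    if len(wt_el) < 3 or len(mut_el) < 3:
        raise ExpressionError("need >= 3 replicates per arm")
    _, p = two_sample_t(mut_el, wt_el, equal_var=equal_var)
    fold = signed_fold(mut_mean, wt_mean, pseudocount=0.0)
    return {"construct_id": mutant.construct_id, "fold": fold, "p_value": p,
            "significant": p < p_max and abs(fold) >= fold_min,
            "wt_mean": wt_mean, "mutant_mean": mut_mean}


# ---------------------------------------------------------------------------
# cross-referencing

def cross_reference(mutated_genes: Mapping[str, set[str]],
                    de_results: Sequence[DEResult]) -> dict:
    """Fraction of mutated genes per origin with significantly altered
    expression, split into up- and down-regulated.

    ``mutated_genes`` maps origin ("somatic"/"germline") to gene sets.
    Fractions are 100 * significant / testable mutated genes, one decimal;
    with no testable gene the fraction is reported as None (NA).
    """
    by_gene = {r.gene_id: r for r in de_results}
    out: dict[str, dict] = {}
    for origin, genes in mutated_genes.items():
        testable = [by_gene[g] for g in sorted(genes)
                    if g in by_gene and by_gene[g].testable]
        sig = [r for r in testable if r.significant]
        up = sum(1 for r in sig if r.signed_fold_change > 0)
        down = sum(1 for r in sig if r.signed_fold_change < 0)
        out[origin] = {
            "mutated_genes": len(genes),
            "testable": len(testable),
            "significant": len(sig),
            "up": up,
            "down": down,
            "pct_significant": (round_half_up(100.0 * len(sig) / len(testable), 1)
                                if testable else None),
        }
    return out


def intersect_driver_panel(mutated_genes: Iterable[str],
                           panel: Iterable[str]) -> set[str]:
    """Case-insensitive intersection of mutated genes with a driver panel.

    Returns the mutated genes' own spelling of shared symbols.
    """
    panel_uc = {g.upper() for g in panel}
    if not panel_uc:
        import warnings
        warnings.warn("driver panel is empty", stacklevel=2)
        return set()
    return {g for g in mutated_genes if g.upper() in panel_uc}


# ---------------------------------------------------------------------------
# I/O

def read_expression_matrix(matrix_path: str | Path,
                           groups_path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Expression TSV (genes x samples, first column gene ids) plus a
    2-column sample/group file with groups in {cancer, normal}."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    gdf = pd.read_csv(groups_path, sep="\t")
    groups = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str)))
    bad = set(groups.values()) - {"cancer", "normal"}
    if bad:
        raise ExpressionError(f"unknown group label(s): {sorted(bad)}")
    return matrix, groups


def read_luciferase_table(path: str | Path) -> dict[str, dict[str, LuciferaseArm]]:
    """Replicate TSV with columns construct, arm, E_f, E_r -> nested arms."""
    # keep_default_na: construct names like "NULL" are real identifiers
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    df["E_f"] = df["E_f"].astype(float)
    df["E_r"] = df["E_r"].astype(float)
    arms: dict[str, dict[str, LuciferaseArm]] = {}
    for (construct, arm), grp in df.groupby(["construct", "arm"], sort=True):
        arms.setdefault(str(construct), {})[str(arm)] = LuciferaseArm(
            construct_id=str(construct), arm=str(arm),
            firefly=tuple(grp["E_f"].astype(float)),
            renilla=tuple(grp["E_r"].astype(float)))
    return arms


def de_results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id, "signed_fold_change": r.signed_fold_change,
        "p_value": r.p_value, "significant": r.significant,
        "testable": r.testable} for r in results])
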