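"""Univariate and multivariate statistics for process-level profiles.

Univariate layer: a Shapiro-Wilk normality gate selects between the parametric
branch (Welch t-test / one-way ANOVA) and the non-parametric branch (Wilcoxon
rank-sum / Kruskal-Wallis).  Both branches are always computed where the data
allow; the gate only decides which p-value is flagged and BH-adjusted.

Multivariate layer: PERMANOVA (pseudo-F), ANOSIM (R) and MRPP (chance-corrected
A) on an arbitrary distance matrix, with a shared seeded label-permutation
engine and p = (1 + #{permuted >= observed}) / (1 + n_permutations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .process_abundance import ProcessAbundanceMatrix
from .table_io import GroupTable

SHAPIRO_ALPHA = 0.05
DEFAULT_PERMUTATIONS = 999

NOT_COMPUTED = float("nan")


# ---------------------------------------------------------------------------
# normality gate

@dataclass
class NormalityGate:
    p_by_group: dict[str, float]  # NaN where not computable
    recommended: str  # "parametric" | "nonparametric"
    reasons: list[str] = field(default_factory=list)


def normality_gate(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = SHAPIRO_ALPHA
) -> NormalityGate:
    """Shapiro-Wilk per group; parametric branch only if every group passes.

    Groups with n < 3 or zero variance cannot be tested and force the
    non-parametric branch with a coded reason.
    """
    ps: dict[str, float] = {}
    reasons: list[str] = []
    parametric = True
    for g, vals in values_by_group.items():
        x = np.asarray(vals, dtype=float)
        if len(x) < 3:
            ps[g] = NOT_COMPUTED
            reasons.append(f"{g}: n < 3")
            parametric = False
        elif np.ptp(x) == 0:
            ps[g] = NOT_COMPUTED
            reasons.append(f"{g}: zero variance")
            parametric = False
        else:
            w, p = stats.shapiro(x)
            ps[g] = float(p)
            if p <= alpha:
                parametric = False
                reasons.append(f"{g}: Shapiro-Wilk p <= {alpha}")
    return NormalityGate(
        p_by_group=ps,
        recommended="parametric" if parametric else "nonparametric",
        reasons=reasons,
    )


# ---------------------------------------------------------------------------
# univariate tests

def two_group_tests(a: Sequence[float], b: Sequence[float]) -> dict[str, float]:
    """Welch t and Wilcoxon rank-sum (Mann-Whitney U), both two-sided.

    Both tests are always attempted; a test whose preconditions fail (n < 2 or
    zero pooled variance for t) reports NaN rather than aborting the other.
    The Wilcoxon p is exact for small tie-free samples, normal-approximated
    with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = {
        "t_statistic": NOT_COMPUTED,
        "t_p": NOT_COMPUTED,
        "wilcoxon_statistic": NOT_COMPUTED,
        "wilcoxon_p": NOT_COMPUTED,
    }
    if len(a) >= 2 and len(b) >= 2 and (np.ptp(a) > 0 or np.ptp(b) > 0):
        t, p = stats.ttest_ind(a, b, equal_var=False)
        out["t_statistic"], out["t_p"] = float(t), float(p)
    if len(a) >= 1 and len(b) >= 1:
        pooled = np.concatenate([a, b])
        if np.ptp(pooled) == 0:
            # every observation tied: no evidence of a shift
            out["wilcoxon_statistic"] = len(a) * len(b) / 2.0
            out["wilcoxon_p"] = 1.0
        else:
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
            out["wilcoxon_statistic"], out["wilcoxon_p"] = float(u), float(p)
    return out


def multi_group_tests(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """One-way fixed-effects ANOVA and tie-corrected Kruskal-Wallis (>= 3 groups)."""
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 3:
        raise ValueError(
            "multi_group_tests requires >= 3 groups; use two_group_tests for 2"
        )
    out = {
        "anova_F": NOT_COMPUTED,
        "anova_p": NOT_COMPUTED,
        "kw_H": NOT_COMPUTED,
        "kw_p": NOT_COMPUTED,
    }
    pooled = np.concatenate(groups)
    if all(len(g) >= 2 for g in groups) and np.ptp(pooled) > 0:
        f, p = stats.f_oneway(*groups)
        out["anova_F"], out["anova_p"] = float(f), float(p)
    if np.ptp(pooled) > 0:
        h, p = stats.kruskal(*groups)
        out["kw_H"], out["kw_p"] = float(h), float(p)
    else:
        out["kw_H"], out["kw_p"] = 0.0, 1.0
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through unadjusted."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# multivariate permutation tests

@dataclass
class MultivariateResult:
    method: str  # PERMANOVA | ANOSIM | MRPP
    statistic: float  # pseudo-F / R / A
    p: float
    n_permutations: int
    seed: int


def _permanova_stats(d2: np.ndarray, label_matrix: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Pseudo-F for each row of group-membership indicator stacks.

    d2: squared distances (n x n); label_matrix: (n_perm, n) integer group ids.
    """
    n = d2.shape[0]
    a = len(sizes)
    ss_total = d2.sum() / (2 * n)
    ss_within = np.zeros(label_matrix.shape[0])
    for g in range(a):
        m = (label_matrix == g).astype(float)  # (n_perm, n)
        within = np.einsum("pi,ij,pj->p", m, d2, m) / 2.0
        ss_within += within / sizes[g]
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def _anosim_stats(rank_d: np.ndarray, label_matrix: np.ndarray) -> np.ndarray:
    """ANOSIM R per permutation from the rank matrix of distances."""
    n = rank_d.shape[0]
    m_pairs = n * (n - 1) / 2
    same = label_matrix[:, :, None] == label_matrix[:, None, :]  # (p, n, n)
    iu = np.triu_indices(n, k=1)
    same_u = same[:, iu[0], iu[1]]
    ranks_u = rank_d[iu]
    within_mean = (same_u * ranks_u).sum(axis=1) / same_u.sum(axis=1)
    between_mean = (~same_u * ranks_u).sum(axis=1) / (~same_u).sum(axis=1)
    return (between_mean - within_mean) / (m_pairs / 2.0)


def _mrpp_deltas(d: np.ndarray, label_matrix: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Weighted mean within-group distance delta per permutation (w_g = n_g/N)."""
    n = d.shape[0]
    deltas = np.zeros(label_matrix.shape[0])
    for g in range(len(sizes)):
        m = (label_matrix == g).astype(float)
        within_sum = np.einsum("pi,ij,pj->p", m, d, m) / 2.0
        n_pairs = sizes[g] * (sizes[g] - 1) / 2
        deltas += (sizes[g] / n) * within_sum / n_pairs
    return deltas


def multivariate_tests(
    d: "DistanceMatrix",
    group: GroupTable,
    method: str = "PERMANOVA",
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> MultivariateResult:
    """Permutation test of group differences on a distance matrix.

    ``method`` is one of PERMANOVA (pseudo-F), ANOSIM (R on distance ranks) or
    MRPP (chance-corrected within-group agreement A).  Group labels are permuted
    ``n_permutations`` times with a seeded generator; for MRPP the extremeness
    direction is a *small* weighted within-group mean distance.
    """
    from .beta_diversity import DistanceMatrix  # circular-safe

    if not isinstance(d, DistanceMatrix):
        raise TypeError("d must be a DistanceMatrix")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    method = method.upper()
    if method not in {"PERMANOVA", "ANOSIM", "MRPP"}:
        raise ValueError(f"unknown method {method!r}")

    labels_raw = group.assignments.reindex(d.sample_ids)
    if labels_raw.isna().any():
        raise ValueError("group table does not cover all samples in the distance matrix")
    group_names = group.groups
    if len(group_names) < 2:
        raise ValueError("multivariate tests need at least 2 groups")
    name_to_id = {g: i for i, g in enumerate(group_names)}
    labels = np.array([name_to_id[g] for g in labels_raw])
    sizes = np.bincount(labels, minlength=len(group_names)).astype(float)
    if (sizes < 2).any():
        raise ValueError("every group needs >= 2 samples")

    rng = np.random.default_rng(seed)
    n = len(labels)
    perms = np.empty((n_permutations, n), dtype=labels.dtype)
    for i in range(n_permutations):
        perms[i] = rng.permutation(labels)
    stacked = np.vstack([labels[None, :], perms])  # row 0 = observed

    dm = d.values
    if method == "PERMANOVA":
        vals = _permanova_stats(dm**2, stacked, sizes)
        observed, permuted = vals[0], vals[1:]
        count = int((permuted >= observed).sum())
        statistic = observed
    elif method == "ANOSIM":
        iu = np.triu_indices(n, k=1)
        rank_flat = stats.rankdata(dm[iu])
        rank_d = np.zeros_like(dm)
        rank_d[iu] = rank_flat
        rank_d = rank_d + rank_d.T
        vals = _anosim_stats(rank_d, stacked)
        observed, permuted = vals[0], vals[1:]
        count = int((permuted >= observed).sum())
        statistic = observed
    else:  # MRPP
        deltas = _mrpp_deltas(dm, stacked, sizes)
        observed, permuted = deltas[0], deltas[1:]
        count = int((permuted <= observed).sum())
        expected = float(permuted.mean())
        statistic = 1.0 - observed / expected if expected > 0 else 0.0

    p = (1 + count) / (1 + n_permutations)
    return MultivariateResult(
        method=method,
        statistic=float(statistic),
        p=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# per-process differential table

@dataclass
class UnivariateResult:
    process_id: str
    n_groups: int
    group_ns: dict[str, int]
    normality_p: dict[str, float]
    parametric: dict[str, float]  # statistic, p
    nonparametric: dict[str, float]  # statistic, p
    recommended: str
    p_raw: float  # recommended branch's raw p (NaN if not computed)
    p_adjusted: float = NOT_COMPUTED
    note: str = ""


def differential_table(
    pam: ProcessAbundanceMatrix,
    group: GroupTable,
    alpha: float = SHAPIRO_ALPHA,
) -> list[UnivariateResult]:
    """One univariate result per process with BH adjustment across processes.

    Two groups dispatch to Welch-t + Wilcoxon, three or more to ANOVA +
    Kruskal-Wallis.  Processes that are all-zero in every sample are reported
    as "not computed" with p = 1 so downstream tables stay rectangular.
    """
    groups = group.groups
    if len(groups) < 2:
        raise ValueError("differential analysis needs at least 2 groups")
    results: list[UnivariateResult] = []
    for pid in pam.process_ids:
        row = pam.values.loc[pid]
        by_group = {g: row[group.samples_in(g)].to_numpy() for g in groups}
        ns = {g: len(v) for g, v in by_group.items()}
        if not (row.to_numpy() > 0).any():
            results.append(
                UnivariateResult(
                    process_id=pid,
                    n_groups=len(groups),
                    group_ns=ns,
                    normality_p={g: NOT_COMPUTED for g in groups},
                    parametric={"statistic": NOT_COMPUTED, "p": NOT_COMPUTED},
                    nonparametric={"statistic": NOT_COMPUTED, "p": NOT_COMPUTED},
                    recommended="nonparametric",
                    p_raw=1.0,
                    note="not computed: process abundance all-zero",
                )
            )
            continue
        gate = normality_gate(by_group, alpha=alpha)
        if len(groups) == 2:
            a, b = (by_group[g] for g in groups)
            t = two_group_tests(a, b)
            parametric = {"statistic": t["t_statistic"], "p": t["t_p"]}
            nonparametric = {"statistic": t["wilcoxon_statistic"], "p": t["wilcoxon_p"]}
        else:
            m = multi_group_tests(by_group)
            parametric = {"statistic": m["anova_F"], "p": m["anova_p"]}
            nonparametric = {"statistic": m["kw_H"], "p": m["kw_p"]}
        recommended = gate.recommended
        p_raw = parametric["p"] if recommended == "parametric" else nonparametric["p"]
        if math.isnan(p_raw) and recommended == "parametric":
            # parametric branch chosen but t/ANOVA not computable: fall back
            recommended = "nonparametric"
            p_raw = nonparametric["p"]
        results.append(
            UnivariateResult(
                process_id=pid,
                n_groups=len(groups),
                group_ns=ns,
                normality_p=gate.p_by_group,
                parametric=parametric,
                nonparametric=nonparametric,
                recommended=recommended,
                p_raw=p_raw,
                note="; ".join(gate.reasons),
            )
        )
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
    return results


def differential_frame(results: list[UnivariateResult]) -> pd.DataFrame:
    """Flatten UnivariateResults into the export table layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "process_id": r.process_id,
                "group_ns": ";".join(f"{g}={n}" for g, n in r.group_ns.items()),
                "normality_ps": ";".join(
                    f"{g}={p:.4g}" if not math.isnan(p) else f"{g}=NA"
                    for g, p in r.normality_p.items()
                ),
                "parametric_stat": r.parametric["statistic"],
                "parametric_p": r.parametric["p"],
                "nonparametric_stat": r.nonparametric["statistic"],
                "nonparametric_p": r.nonparametric["p"],
                "recommended": r.recommended,
                "p_raw": r.p_raw,
                "p_adj": r.p_adjusted,
                "note": r.note,
            }
        )
    return pd.DataFrame(rows).set_index("process_id")
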