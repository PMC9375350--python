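"""Multiple imputation of unobserved follow-up intervals.

Children absent or dropped at baseline or a follow-up have no
transition counts for that interval.  The imputation model is a
hot-deck within risk stratum: each missing child-interval draws a
donor uniformly at random from the children of the same risk stratum
with an observed interval at the same visit, and copies the donor's
(P, R, N) counts.  This operates at the transition-counts level — all
downstream statistics (ADJCI, stratum means, ANOVA) are functions of
the counts — so no surface-level trajectories are invented.

The hot-deck is a declared, simple stand-in for a full
chained-equations model; it respects the risk structure that drives
increments and is unbiased under missingness-completely-at-random.
Pooling across the m completed datasets follows Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CohortFrame
from .transitions import Cutoff, cohort_transition_table

__all__ = [
    "ImputationSet",
    "PooledEstimate",
    "IrreducibleMissingnessError",
    "observed_counts",
    "impute",
    "pool",
]


class IrreducibleMissingnessError(ValueError):
    """A stratum has a missing interval but no observed donor."""


@dataclass(frozen=True)
class ImputationSet:
    """m completed per-child transition-counts tables.

    Each dataset has columns ``child_id, risk, visit, cutoff, P, R, N,
    imputed``; observed rows are identical across all m datasets, only
    imputed rows differ.
    """

    m: int
    datasets: tuple[pd.DataFrame, ...]
    seed: int

    def stacked(self) -> pd.DataFrame:
        """All datasets stacked with an ``imputation`` index column."""
        out = []
        for i, d in enumerate(self.datasets):
            d = d.copy()
            d.insert(0, "imputation", i)
            out.append(d)
        return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of m (estimate, variance) pairs."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int


def observed_counts(
    cohort: CohortFrame,
    cutoffs: tuple[Cutoff, ...] = (Cutoff.CAV_3_6, Cutoff.ALL_A_6),
    visits: tuple[int, ...] = (1, 2, 3),
) -> pd.DataFrame:
    """Observed per-child P/R/N for every cutoff x follow-up interval."""
    frames = [
        cohort_transition_table(cohort, cut, v) for cut in cutoffs for v in visits
    ]
    return pd.concat(frames, ignore_index=True)


def impute(
    cohort: CohortFrame,
    m: int = 20,
    seed: int = 0,
    cutoffs: tuple[Cutoff, ...] = (Cutoff.CAV_3_6, Cutoff.ALL_A_6),
    visits: tuple[int, ...] = (1, 2, 3),
) -> ImputationSet:
    """Hot-deck-within-stratum multiple imputation of missing intervals.

    Reproducible: the same cohort, m and seed give bit-identical
    datasets.  Donors are drawn per missing child-interval; the same
    donor supplies all cutoffs for that child-interval so the imputed
    counts stay internally consistent.

    Raises
    ------
    IrreducibleMissingnessError
        If some stratum has a missing interval but no donor at that
        visit.
    """
    if m < 2:
        raise ValueError("multiple imputation needs m >= 2")
    cutoffs = tuple(Cutoff(c) for c in cutoffs)
    obs = observed_counts(cohort, cutoffs, visits)
    risk_of = cohort.risk_of()
    all_children = cohort.children["child_id"].tolist()

    # Missing child-intervals: child x visit pairs with no observed counts.
    observed_pairs = set(zip(obs["child_id"], obs["visit"]))
    missing = [
        (cid, v)
        for v in visits
        for cid in all_children
        if (cid, v) not in observed_pairs
    ]

    donors: dict[tuple[str, int], list[str]] = {}
    one_cut = obs[obs["cutoff"] == cutoffs[0].value]
    for (risk, v), grp in one_cut.groupby(["risk", "visit"]):
        donors[(risk, v)] = sorted(grp["child_id"].tolist())
    problems = sorted(
        {
            (risk_of[cid], v)
            for cid, v in missing
            if not donors.get((risk_of[cid], v))
        }
    )
    if problems:
        raise IrreducibleMissingnessError(
            f"no donors for stratum x visit pairs: {problems}"
        )

    obs_indexed = obs.set_index(["child_id", "visit", "cutoff"]).sort_index()
    rng = np.random.default_rng(seed)
    datasets = []
    for _ in range(m):
        rows = []
        for cid, v in missing:
            pool_ids = donors[(risk_of[cid], v)]
            donor = pool_ids[rng.integers(len(pool_ids))]
            for cut in cutoffs:
                d = obs_indexed.loc[(donor, v, cut.value)]
                rows.append(
                    {
                        "child_id": cid,
                        "risk": risk_of[cid],
                        "visit": v,
                        "cutoff": cut.value,
                        "P": int(d["P"]),
                        "R": int(d["R"]),
                        "N": int(d["N"]),
                        "imputed": True,
                    }
                )
        base = obs.copy()
        base["imputed"] = False
        if rows:
            completed = pd.concat(
                [base, pd.DataFrame(rows, columns=base.columns)], ignore_index=True
            )
        else:
            completed = base
        completed = completed.sort_values(
            ["cutoff", "visit", "child_id"], kind="mergesort"
        ).reset_index(drop=True)
        datasets.append(completed)
    return ImputationSet(m=m, datasets=tuple(datasets), seed=seed)


def pool(estimates, variances, df_complete: float | None = None) -> PooledEstimate:
    """Combine m per-dataset estimates by Rubin's rules.

    total variance T = W + (1 + 1/m) B, with W the mean within-dataset
    variance and B the between-dataset variance of the estimates.  The
    df is Rubin's (m-1)(1 + W/((1+1/m)B))^2, with the Barnard-Rubin
    small-sample adjustment when ``df_complete`` is given.  B = 0
    (identical estimates) gives infinite df.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.ndim != 1 or q.shape != u.shape or q.size < 2:
        raise ValueError("need m >= 2 paired (estimate, variance) values")
    m = q.size
    qbar = q.mean()
    w = u.mean()
    b = ((q - qbar) ** 2).sum() / (m - 1)
    t = w + (1 + 1 / m) * b

    if b == 0:
        df = np.inf
    else:
        r = (1 + 1 / m) * b
        df = (m - 1) * (1 + w / r) ** 2
        if df_complete is not None:
            lam = r / t
            df_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
            df = 1 / (1 / df + 1 / df_obs)
    return PooledEstimate(
        estimate=float(qbar),
        within_var=float(w),
        between_var=float(b),
        total_var=float(t),
        df=float(df),
        m=m,
    )
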