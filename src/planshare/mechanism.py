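"""Infer plan cost-sharing mechanism design and classify plans.

A claims database shows each plan's adjudicated cost sharing but not the
benefit design printed on the insurance card. Because every enrollee of a
plan is observed, the design can be inferred: the *mode* copay across the
plan's claims, the *mode* coinsurance percentage (per-claim coinsurance over
allowed amount), and the *maximum* annual deductible accumulated by any
enrollee. Each plan is thus a triplet (mode copay, mode coinsurance rate,
max deductible), min-max scaled per component, and clustered with a
4-center k-means whose initialisation is 3 random centers plus one
deterministic center at the origin. Clusters are labeled balanced / copay- /
coinsurance- / deductible-dominated, and the four types are ranked by mean
annual out-of-pocket cost.

Scaling orientation: the study's printed formula,
``(max - x) / (max - min)``, sends the component *maximum* to 0 — the
reverse of conventional min-max scaling. Both orientations are provided
(``as_printed`` is the default); cluster labeling undoes the inversion
before interpreting center coordinates, so type labels are orientation-
independent for well-separated plans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import COST_FIELDS
from .errors import InvalidInputError
from .rng import substream

__all__ = [
    "ClusterModel",
    "compute_plan_triplets",
    "scale_triplets",
    "kmeans_classify",
    "label_clusters",
    "rank_plan_types",
    "classify_plans",
]

log = logging.getLogger(__name__)

COMPONENTS = ["mode_copay", "mode_coinsurance_rate", "max_deductible"]
SCALED = ["s_copay", "s_coinsurance", "s_deductible"]
#: triplet dimension -> plan-type label for dominance labeling
_DIM_TYPE = {0: "copay", 1: "coinsurance", 2: "deductible"}


@dataclass
class ClusterModel:
    """Fitted 4-center k-means over scaled plan triplets."""

    centers: np.ndarray  # (4, 3)
    assignments: pd.Series  # plan_id -> cluster index
    n_iterations: int
    seed: int
    sse_history: list[float] = field(default_factory=list)
    reseed_events: list[tuple[int, int]] = field(default_factory=list)  # (iteration, cluster)

    @property
    def sse(self) -> float:
        return self.sse_history[-1] if self.sse_history else float("nan")


def _mode_smallest(values: pd.Series) -> float:
    """Most frequent value; ties broken toward the smaller value."""
    counts = values.value_counts()
    top = counts[counts == counts.max()]
    return float(min(top.index))


def compute_plan_triplets(
    claims: pd.DataFrame,
    exclude_zero_cost_claims: bool = False,
) -> pd.DataFrame:
    """Mechanism-design triplet for every plan present in the claims.

    mode copay: most frequent per-claim copay. mode coinsurance rate: most
    frequent value of coinsurance / allowed (claims with zero allowed amount
    skipped; ratios rounded to 2 decimals first, since real rates are quoted
    in whole percents). max deductible: the largest annual deductible total
    accumulated by any single enrollee. Mode ties break toward the smaller
    value. ``exclude_zero_cost_claims`` drops claims with no patient cost
    share before the mode computations.
    """
    c = claims.copy()
    if len(c) == 0:
        raise InvalidInputError("claims table is empty")
    c["service_date"] = pd.to_datetime(c["service_date"])
    c["year"] = c["service_date"].dt.year

    base = c
    if exclude_zero_cost_claims:
        base = c[c[COST_FIELDS].sum(axis=1) > 0]

    mode_copay = base.groupby("plan_id")["copay"].agg(_mode_smallest)

    ratio = base[base["allowed_amount"] > 0].copy()
    ratio["coins_rate"] = (ratio["coinsurance"] / ratio["allowed_amount"]).round(2)
    mode_rate = ratio.groupby("plan_id")["coins_rate"].agg(_mode_smallest)

    annual_ded = (
        c.groupby(["plan_id", "enrollee_id", "year"])["deductible"].sum().reset_index()
    )
    max_ded = annual_ded.groupby("plan_id")["deductible"].max()

    out = pd.DataFrame(
        {
            "plan_id": mode_copay.index,
            "mode_copay": mode_copay.to_numpy(),
        }
    )
    out["mode_coinsurance_rate"] = out["plan_id"].map(mode_rate).fillna(0.0)
    out["max_deductible"] = out["plan_id"].map(max_ded).fillna(0.0)
    out["n_enrollees"] = out["plan_id"].map(c.groupby("plan_id")["enrollee_id"].nunique())
    out["n_claims"] = out["plan_id"].map(c.groupby("plan_id").size())
    return out.reset_index(drop=True)


def scale_triplets(
    triplets: pd.DataFrame, orientation: str = "as_printed"
) -> pd.DataFrame:
    """Component-wise min-max scaling of the plan triplets to [0, 1].

    ``as_printed`` uses (max - x)/(max - min), so the plan attaining a
    component's global maximum scales to 0; ``standard`` uses the
    conventional (x - min)/(max - min). A degenerate component (max == min)
    maps to 0 for all plans, with a warning.
    """
    if orientation not in ("as_printed", "standard"):
        raise InvalidInputError(f"unknown orientation {orientation!r}")
    out = triplets[["plan_id"]].copy()
    for raw, scaled in zip(COMPONENTS, SCALED):
        x = triplets[raw].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            log.warning("component %s is degenerate (all values %.4g); scaled to 0", raw, lo)
            out[scaled] = 0.0
        elif orientation == "as_printed":
            out[scaled] = (hi - x) / (hi - lo)
        else:
            out[scaled] = (x - lo) / (hi - lo)
    return out


def _sse(X: np.ndarray, centers: np.ndarray, assign: np.ndarray) -> float:
    return float(((X - centers[assign]) ** 2).sum())


def kmeans_classify(
    scaled: pd.DataFrame,
    seed: int = 0,
    max_iter: int = 300,
    pin_origin: bool = False,
    init_centers: np.ndarray | None = None,
    n_restarts: int = 1,
) -> ClusterModel:
    """Lloyd's k-means with 3 random centers plus one center at the origin.

    Points are assigned to the exactly nearest center in Euclidean distance;
    all four centers (including the origin-seeded one, unless ``pin_origin``)
    are then recomputed as the means of their assigned points, and the loop
    repeats until no assignment changes. A cluster left empty after an
    assignment step is re-seeded to the point farthest from its nearest
    center. ``init_centers`` overrides the initialisation (used by the
    step-by-step oracle tests).

    The default single run follows the described procedure exactly, but
    Lloyd iteration can converge to a poor basin from an unlucky random
    init; ``n_restarts > 1`` draws additional seed-derived inits and keeps
    the run with the lowest final within-cluster SSE.
    """
    if n_restarts < 1:
        raise InvalidInputError("n_restarts must be >= 1")
    if n_restarts > 1 and init_centers is None:
        best: ClusterModel | None = None
        for r in range(n_restarts):
            rng = substream(seed, "kmeans" if r == 0 else f"kmeans-restart-{r}")
            init = np.vstack([rng.uniform(0.0, 1.0, size=(3, 3)), np.zeros((1, 3))])
            model = kmeans_classify(
                scaled, seed=seed, max_iter=max_iter,
                pin_origin=pin_origin, init_centers=init,
            )
            if best is None or model.sse < best.sse:
                best = model
        best.seed = seed
        return best

    X = scaled[SCALED].to_numpy(dtype=float)
    n = len(X)
    if n < 4:
        raise InvalidInputError("need at least 4 plans to form 4 clusters")
    if init_centers is not None:
        centers = np.asarray(init_centers, dtype=float).copy()
        if centers.shape != (4, 3):
            raise InvalidInputError("init_centers must have shape (4, 3)")
    else:
        rng = substream(seed, "kmeans")
        centers = np.vstack([rng.uniform(0.0, 1.0, size=(3, 3)), np.zeros((1, 3))])

    assign = np.full(n, -1, dtype=int)
    sse_history: list[float] = []
    reseeds: list[tuple[int, int]] = []
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        # empty-cluster repair: farthest point from its nearest center
        for k in range(4):
            if not (new_assign == k).any():
                nearest = d2.min(axis=1)
                far = int(nearest.argmax())
                centers[k] = X[far]
                reseeds.append((it, k))
                log.info("iteration %d: cluster %d empty; re-seeded", it, k)
                d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
                new_assign = d2.argmin(axis=1)
        sse_history.append(_sse(X, centers, new_assign))
        if (new_assign == assign).all():
            break
        assign = new_assign
        for k in range(4):
            if pin_origin and k == 3:
                continue
            pts = X[assign == k]
            if len(pts):
                centers[k] = pts.mean(axis=0)
    return ClusterModel(
        centers=centers,
        assignments=pd.Series(assign, index=scaled["plan_id"].to_numpy(), name="cluster"),
        n_iterations=n_iter,
        seed=seed,
        sse_history=sse_history,
        reseed_events=reseeds,
    )


def label_clusters(
    model: ClusterModel, orientation: str = "as_printed"
) -> dict[int, str]:
    """Map cluster index -> plan-type label from the center geometry.

    Centers are first re-expressed so that larger coordinates mean more cost
    sharing (undoing the printed scaling's inversion). The cluster whose
    re-expressed center has the smallest across-dimension range is labeled
    ``balanced``; each remaining cluster takes the plan type of its largest
    coordinate, with conflicts resolved greedily — the cluster with the
    larger coordinate keeps the dimension, the loser takes its largest
    unclaimed one.
    """
    centers = model.centers.copy()
    if orientation == "as_printed":
        centers = 1.0 - centers
    elif orientation != "standard":
        raise InvalidInputError(f"unknown orientation {orientation!r}")

    ranges = centers.max(axis=1) - centers.min(axis=1)
    balanced = int(ranges.argmin())
    labels = {balanced: "balanced"}
    remaining = [k for k in range(4) if k != balanced]
    unclaimed = set(_DIM_TYPE)
    while remaining:
        best = max(
            ((k, d, centers[k, d]) for k in remaining for d in unclaimed),
            key=lambda t: (t[2], -t[0], -t[1]),
        )
        k, d, _ = best
        labels[k] = _DIM_TYPE[d]
        remaining.remove(k)
        unclaimed.remove(d)
    return labels


def rank_plan_types(
    assignments: pd.DataFrame,
    enrollee_annual_oopc: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank plan types by mean annual out-of-pocket cost, ascending.

    The type statistic is a mean of plan means: average annual OOPC over each
    plan's enrollees, then the unweighted average of those plan averages over
    the type's plans. Returns ``(assignments with oopc_rank, type_stats)``.

    ``assignments`` needs columns plan_id, plan_type;
    ``enrollee_annual_oopc`` needs enrollee_id, plan_id, oopc_all_medical.
    """
    plan_mean = (
        enrollee_annual_oopc.groupby("plan_id")["oopc_all_medical"].mean().rename("plan_mean_oopc")
    )
    a = assignments.merge(plan_mean, on="plan_id", how="left")
    type_stats = (
        a.groupby("plan_type")["plan_mean_oopc"].mean().rename("mean_oopc").reset_index()
    )
    type_stats = type_stats.sort_values("mean_oopc").reset_index(drop=True)
    type_stats["oopc_rank"] = np.arange(1, len(type_stats) + 1)
    a = a.merge(type_stats[["plan_type", "oopc_rank"]], on="plan_type", how="left")
    return a.drop(columns=["plan_mean_oopc"]), type_stats


def classify_plans(
    claims: pd.DataFrame,
    enrollee_annual_oopc: pd.DataFrame | None = None,
    seed: int = 0,
    orientation: str = "as_printed",
    **kmeans_kwargs,
) -> tuple[pd.DataFrame, ClusterModel, pd.DataFrame | None]:
    """Triplets -> scaling -> k-means -> labels -> (optional) OOPC ranking.

    Returns ``(assignments, model, type_stats)``; type_stats is None when no
    enrollee OOPC table is supplied.
    """
    triplets = compute_plan_triplets(claims)
    scaled = scale_triplets(triplets, orientation)
    model = kmeans_classify(scaled, seed=seed, **kmeans_kwargs)
    labels = label_clusters(model, orientation)
    assignments = pd.DataFrame(
        {
            "plan_id": model.assignments.index,
            "cluster": model.assignments.to_numpy(),
        }
    )
    assignments["plan_type"] = assignments["cluster"].map(labels)
    type_stats = None
    if enrollee_annual_oopc is not None:
        assignments, type_stats = rank_plan_types(assignments, enrollee_annual_oopc)
    return assignments, model, type_stats
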