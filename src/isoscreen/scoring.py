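"""Inhibition scoring, replicate aggregation, hit calling and clustering.

The screen's normalization statistic is the Inhibition score

    I-score(c) = (1 - signal(c) / median(signal_DMSO)) * 100

i.e. percent growth inhibition relative to the vehicle wells: 0 at the DMSO
median, 100 at zero signal, negative under growth stimulation (never
clipped). Hits are compounds exceeding 50% inhibition in at least one line;
line-selective hits exceed it in exactly one line and stay strictly below
it in every other. Inhibition profiles are clustered with complete linkage
on Euclidean distances, as is conventional for screen heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .plate_io import ScreenDataset

__all__ = [
    "IScoreRecord",
    "InhibitionProfile",
    "HitCall",
    "i_score",
    "score_screen",
    "aggregate",
    "build_profile",
    "efficacy_filter",
    "selectivity_class",
    "call_hits",
    "cluster_profiles",
    "ClusterResult",
]


def i_score(signal: float, dmso_signals: Iterable[float]) -> float:
    """Percent inhibition of one well relative to the DMSO median.

    Exact formula value, no clipping; an even number of controls takes the
    mean of the central two as the median.
    """
    dmso = np.asarray(list(dmso_signals), dtype=float)
    if dmso.size == 0:
        raise ValueError("empty DMSO signal set")
    med = float(np.median(dmso))
    if med <= 0:
        raise ValueError(f"DMSO median must be positive, got {med}")
    return (1.0 - float(signal) / med) * 100.0


@dataclass(frozen=True)
class IScoreRecord:
    compound_id: str
    cell_line_id: str
    dose_um: float
    i_score: float
    n_replicates: int
    sd: float


def score_screen(dataset: ScreenDataset, pool: str = "plate") -> pd.DataFrame:
    """Per-well I-scores for every treated well of a screen.

    ``pool`` chooses the DMSO baseline: "plate" (default; controls share
    plate effects with their treated wells) normalizes each well against the
    control median of its own plate, "run" against all controls of the same
    cell line pooled across plates.
    """
    if pool not in ("plate", "run"):
        raise ValueError(f"pool must be 'plate' or 'run', got {pool!r}")
    df = dataset.records
    ctrl = dataset.controls()
    if pool == "plate":
        med = ctrl.groupby("plate_id")["luminescence"].median()
        keys = df["plate_id"].map(med)
    else:
        med = ctrl.groupby("cell_line")["luminescence"].median()
        keys = df["cell_line"].map(med)
    if keys.isna().any() or (keys <= 0).any():
        raise ValueError("missing or non-positive DMSO median for some wells")
    out = dataset.treated().copy()
    out["i_score"] = (1.0 - out["luminescence"] / keys.loc[out.index]) * 100.0
    return out[["plate_id", "well", "cell_line", "compound", "dose_um", "replicate", "i_score"]]


def aggregate(scored: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate wells to one record per (compound, line, dose).

    Returns mean I-score and the sample standard deviation across replicate
    wells (0 when a single replicate is present).
    """
    grp = scored.groupby(["compound", "cell_line", "dose_um"], sort=True)["i_score"]
    out = grp.agg(i_score="mean", n_replicates="size", sd=lambda s: s.std(ddof=1)).reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out


@dataclass
class InhibitionProfile:
    """Compound x cell-line matrix of aggregated I-scores.

    ``matrix`` rows are compounds, columns the panel lines; ``metadata``
    records the dose-aggregation rule used to build it.
    """

    matrix: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix.isna().any().any():
            raise ValueError("profile has missing values (incomplete panel rows)")

    @property
    def compounds(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def panel(self) -> list[str]:
        return list(self.matrix.columns)


def build_profile(
    aggregated: pd.DataFrame,
    panel: Iterable[str] | None = None,
    dose_aggregation: str = "max",
    dose_um: float | None = None,
) -> InhibitionProfile:
    """Pivot aggregated I-scores into a compound x line profile.

    ``dose_aggregation`` is "max" (a compound active at either screened dose
    counts; the default) or "dose" with an explicit ``dose_um``.
    """
    df = aggregated
    if dose_aggregation == "dose":
        if dose_um is None:
            raise ValueError("dose_aggregation='dose' requires dose_um")
        df = df[df["dose_um"] == dose_um]
        meta = {"dose_aggregation": "dose", "dose_um": dose_um}
    elif dose_aggregation == "max":
        meta = {"dose_aggregation": "max_over_dose"}
    else:
        raise ValueError(f"unknown dose_aggregation {dose_aggregation!r}")
    mat = df.pivot_table(index="compound", columns="cell_line", values="i_score", aggfunc="max")
    if panel is not None:
        mat = mat.reindex(columns=list(panel))
    mat.index.name = "compound"
    return InhibitionProfile(matrix=mat, metadata=meta)


def efficacy_filter(profile: InhibitionProfile, threshold: float = 50.0) -> pd.Series:
    """Efficacious <=> I-score strictly above threshold in >= 1 line."""
    return (profile.matrix > threshold).any(axis=1)


def selectivity_class(profile_row: Mapping[str, float], threshold: float = 50.0) -> str:
    """Classify one compound's panel profile.

    Returns ``"<line>_selective"`` when the score strictly exceeds the
    threshold in exactly that line and is strictly below it in all others,
    ``"pan_active"`` when all lines exceed it, ``"inactive"`` when none
    does, otherwise ``"other_selective_pattern"``. Scores exactly at the
    threshold pass neither strict test.
    """
    row = dict(profile_row)
    above = [ln for ln, v in row.items() if v > threshold]
    below = [ln for ln, v in row.items() if v < threshold]
    if not above:
        return "inactive"
    if len(above) == len(row):
        return "pan_active"
    if len(above) == 1 and len(below) == len(row) - 1:
        return f"{above[0]}_selective"
    return "other_selective_pattern"


@dataclass(frozen=True)
class HitCall:
    compound_id: str
    efficacious: bool
    selectivity_class: str


def call_hits(profile: InhibitionProfile, threshold: float = 50.0) -> list[HitCall]:
    """Efficacy filter + selectivity classification over a whole profile."""
    eff = efficacy_filter(profile, threshold)
    calls = []
    for cid, row in profile.matrix.iterrows():
        if not eff[cid]:
            calls.append(HitCall(cid, False, "inactive"))
        else:
            calls.append(HitCall(cid, True, selectivity_class(row.to_dict(), threshold)))
    return calls


# ---------------------------------------------------------------------------
# complete-linkage clustering of inhibition profiles
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Agglomerative merge trace and deterministic leaf ordering.

    ``merges`` lists (members_left, members_right, height) in merge order,
    each member tuple sorted; heights are complete-linkage (max pairwise
    Euclidean) distances.
    """

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    leaf_order: list[str]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


def cluster_profiles(profile: InhibitionProfile) -> ClusterResult:
    """Complete-linkage agglomeration of compound rows, Euclidean metric.

    Deterministic: among equal-distance candidate pairs, the pair whose
    (smallest-member, smallest-member) compound-id tuple sorts first is
    merged. Leaf order puts the cluster with the lexicographically smaller
    minimum id on the left at every merge.
    """
    mat = profile.matrix
    ids = list(mat.index)
    if len(ids) < 2:
        raise ValueError("need at least 2 compounds to cluster")
    X = mat.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("NaN/inf in profile matrix")

    # cluster state: members (sorted tuples) and complete-linkage distances,
    # maintained with the Lance-Williams update D_new = max(D_i, D_j)
    members: list[tuple[str, ...]] = [(cid,) for cid in ids]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(D, np.inf)
    active = list(range(len(ids)))
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    children: dict[int, tuple[int, int]] = {}
    next_id = len(ids)
    node_of = {i: i for i in active}  # cluster slot -> tree node id
    min_id = {i: ids[i] for i in active}

    while len(active) > 1:
        sub = D[np.ix_(active, active)]
        h = sub.min()
        cand = []
        for ai, aj in np.argwhere(sub <= h + 1e-12):
            if ai < aj:
                i, j = active[ai], active[aj]
                cand.append((tuple(sorted((min_id[i], min_id[j]))), i, j))
        _, i, j = min(cand)
        left, right = (i, j) if min_id[i] <= min_id[j] else (j, i)
        merges.append((members[left], members[right], float(D[i, j])))
        # merge j into i
        newd = np.maximum(D[i, :], D[j, :])
        D[i, :] = newd
        D[:, i] = newd
        D[i, i] = np.inf
        members[i] = tuple(sorted(members[left] + members[right]))
        children[next_id] = (node_of[left], node_of[right])
        node_of[i] = next_id
        min_id[i] = min(min_id[i], min_id[j])
        next_id += 1
        active.remove(j)

    # in-order traversal for the leaf ordering
    order: list[str] = []

    def walk(node: int) -> None:
        if node < len(ids):
            order.append(ids[node])
        else:
            l, r = children[node]
            walk(l)
            walk(r)

    walk(node_of[active[0]])
    return ClusterResult(merges=merges, leaf_order=order)
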