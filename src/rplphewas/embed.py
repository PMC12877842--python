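"""UMAP embedding of non-pregnancy diagnosis profiles and rank-sum tests.

Patients' binary diagnosis profiles — with every "pregnancy complications"
Phecode column removed first, so the projection reflects diagnoses leading
to the outcome rather than indicating it — are embedded into two dimensions
with UMAP. Coordinate distributions are then compared between groups
(RPL vs control, <35 vs 35+) with two-sided Wilcoxon rank-sum tests, one
per embedding dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phenome import PREGNANCY_CATEGORY, PhenomeMatrix


@dataclass
class EmbeddingResult:
    coords: pd.DataFrame  # person_id, dim1, dim2, group, stratum
    params: dict = field(default_factory=dict)
    tests: pd.DataFrame | None = None


def embed_patients(
    matrix: PhenomeMatrix,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    metric: str = "euclidean",
    age_cutoff: float = 35.0,
) -> EmbeddingResult:
    """2-D UMAP of the presence matrix; deterministic given seed and input.

    Refuses matrices that still contain pregnancy-complication columns
    (callers must apply :func:`rplphewas.phenome.drop_category` first) and
    matrices with fewer than 4 patients (the neighborhood graph is
    undefined). Hyperparameters are common defaults, recorded in
    ``params``. Random initialization is used so degenerate inputs (e.g.,
    identical rows) still embed to finite coordinates.
    """
    if (matrix.diagnoses["category"] == PREGNANCY_CATEGORY).any():
        raise ValueError(
            "matrix still contains 'pregnancy complications' columns; "
            "drop_category() must be applied before embedding"
        )
    X = matrix.presence.to_numpy(dtype=np.float32)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 patients to embed")

    import umap

    nn = min(n_neighbors, X.shape[0] - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2, n_neighbors=nn, min_dist=min_dist, metric=metric,
            random_state=seed, init="random",
        )
        coords = reducer.fit_transform(X)

    patients = matrix.patients.set_index("person_id").loc[matrix.presence.index]
    out = pd.DataFrame(
        {
            "person_id": matrix.presence.index,
            "dim1": coords[:, 0],
            "dim2": coords[:, 1],
            "group": patients["group"].to_numpy(),
        }
    )
    if "age_at_index" in patients:
        out["stratum"] = np.where(
            patients["age_at_index"].to_numpy() < age_cutoff, "under35", "over35"
        )
    result = EmbeddingResult(
        coords=out,
        params={
            "n_neighbors": nn, "min_dist": min_dist, "metric": metric,
            "seed": seed, "init": "random",
        },
    )
    tests = []
    for label_col, comparison in (("group", "rpl_vs_control"),
                                  ("stratum", "under35_vs_over35")):
        if label_col in out and out[label_col].nunique() == 2:
            pvals = ranksum_by_group(out[["dim1", "dim2"]], out[label_col])
            for dim, p in pvals.items():
                tests.append({"comparison": comparison, "dimension": dim, "p": p})
    result.tests = pd.DataFrame(tests, columns=["comparison", "dimension", "p"])
    return result


def ranksum_by_group(coords: pd.DataFrame, labels) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum p-value per embedding dimension."""
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    a, b = (labels == levels[0]), (labels == levels[1])
    out = {}
    for dim in coords.columns:
        x, y = coords.loc[a, dim], coords.loc[b, dim]
        out[dim] = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return out
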