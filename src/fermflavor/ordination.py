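"""PCA ordination of samples from OTU abundance.

Samples close together in the score plot have similar community
composition. Counts are first carried to a composition-aware scale
(per-sample relative abundance by default; Hellinger square-root or a
centered log-ratio with pseudocount optionally), features are centered,
and the decomposition is by singular values. Component signs are fixed by
forcing the largest-magnitude loading of each component to be positive, so
results are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .otu import OtuTable

TRANSFORMS = ("relative", "hellinger", "clr_pseudocount")


@dataclass
class PcaResult:
    scores: pd.DataFrame  # sample x component
    loadings: pd.DataFrame  # feature x component
    explained_variance_ratio: pd.Series
    transform: str
    centered: bool = True

    @property
    def components(self) -> list[str]:
        return list(self.scores.columns)


def transform_counts(
    otus: OtuTable, transform: str = "relative", pseudocount: float = 0.5
) -> pd.DataFrame:
    """Sample x feature matrix on the requested scale."""
    if transform not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}")
    rel = otus.relative_abundance().T  # samples x OTUs
    if transform == "relative":
        return rel
    if transform == "hellinger":
        return np.sqrt(rel)
    shifted = otus.counts.T + pseudocount
    log = np.log(shifted)
    return log.sub(log.mean(axis=1), axis=0)


def pca(
    otus: OtuTable,
    transform: str = "relative",
    n_components: int = 2,
    pseudocount: float = 0.5,
) -> PcaResult:
    """Principal component analysis of samples with deterministic signs."""
    x = transform_counts(otus, transform=transform, pseudocount=pseudocount)
    n_samples, n_features = x.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_comp = min(n_samples - 1, n_features)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, {max_comp}] for {n_samples} samples "
            f"x {n_features} features"
        )

    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x.to_numpy())
    loadings = model.components_.T  # feature x component

    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=x.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=x.columns, columns=comp_names),
        explained_variance_ratio=pd.Series(
            model.explained_variance_ratio_, index=comp_names
        ),
        transform=transform,
    )
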