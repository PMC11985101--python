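"""Soil chemistry tables and the topology-chemistry ordination.

Links network topology to soil chemistry at the ecosystem level: replicate
chemistry records are averaged per ecosystem, joined with the topology
summary and per-domain Shannon diversity into an ecosystem x feature
matrix, and ordinated by PCA on z-scored columns (topology counts and
chemistry concentrations differ by orders of magnitude, so the correlation
matrix, not the covariance, is decomposed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .reference import CHEMISTRY_TRAITS


class ChemistryError(ValueError):
    pass


#: Default ecosystem-level feature set entering the ordination.
DEFAULT_FEATURES = [
    "modularity_Q", "n_modules", "diameter", "average_path_length",
    "average_clustering", "n_edges", "n_nodes", "average_degree",
    "shannon_bacteria", "shannon_fungi",
    "pH", "TN", "OC", "P2O5",
]


def cn_ratio(oc, tn):
    """Carbon-to-nitrogen ratio OC/TN (both g/kg); display-rounds to 0.1.

    Accepts scalars or aligned array-likes. TN must be strictly positive.
    """
    oc_arr = np.asarray(oc, dtype=float)
    tn_arr = np.asarray(tn, dtype=float)
    if (tn_arr <= 0).any():
        raise ChemistryError("total nitrogen must be > 0 to form C/N")
    ratio = oc_arr / tn_arr
    if np.isscalar(oc) or oc_arr.ndim == 0:
        return float(ratio)
    if isinstance(oc, pd.Series):
        return pd.Series(ratio, index=oc.index, name="CN")
    return ratio


def validate_chemistry(chem: pd.DataFrame) -> pd.DataFrame:
    """Check physical ranges of a per-record chemistry table.

    Texture fractions must sum to <= 1000 g/kg (2% rounding tolerance),
    pH in [3, 10], all mass/charge traits non-negative. Adds derived CN
    when missing. Returns the (possibly augmented) table.
    """
    chem = chem.copy()
    if "ecosystem" not in chem.columns:
        raise ChemistryError("chemistry table needs an 'ecosystem' column")
    texture = [c for c in ("sand", "loam", "clay") if c in chem.columns]
    if len(texture) == 3:
        tot = chem[texture].sum(axis=1)
        if (tot > 1000 * 1.02).any():
            bad = chem.loc[tot > 1020, "ecosystem"].tolist()
            raise ChemistryError(f"sand+loam+clay exceeds 1000 g/kg for {bad}")
    if "pH" in chem.columns and ((chem["pH"] < 3) | (chem["pH"] > 10)).any():
        raise ChemistryError("pH outside [3, 10]")
    mass_cols = [c for c in CHEMISTRY_TRAITS if c in chem.columns and c not in ("pH", "CN")]
    if (chem[mass_cols] < 0).to_numpy().any():
        raise ChemistryError("negative mass/charge trait values")
    if "CN" not in chem.columns and {"OC", "TN"} <= set(chem.columns):
        chem["CN"] = cn_ratio(chem["OC"], chem["TN"])
    return chem


def aggregate_chemistry(chem: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of replicate records per ecosystem."""
    chem = validate_chemistry(chem)
    numeric = chem.drop(columns=["replicate"], errors="ignore")
    return numeric.groupby("ecosystem").mean(numeric_only=True)


def assemble_feature_matrix(
    topology: pd.DataFrame,
    chemistry: pd.DataFrame,
    diversity: pd.DataFrame | None = None,
    features: Sequence[str] = DEFAULT_FEATURES,
) -> pd.DataFrame:
    """Ecosystem x feature matrix joining topology, chemistry and diversity.

    ``topology`` is a summary table indexed by ecosystem; ``chemistry`` may
    be per-replicate (averaged here) or already per-ecosystem; ``diversity``
    holds per-ecosystem mean Shannon H' with columns ``shannon_bacteria`` /
    ``shannon_fungi``. Ecosystem labels must align; mismatches raise and
    name the offenders.
    """
    if len(topology) < 3:
        raise ChemistryError("need >= 3 ecosystems for an ordination")
    chem = chemistry
    if "ecosystem" in chem.columns:
        chem = aggregate_chemistry(chem)
    missing = topology.index.difference(chem.index)
    if len(missing):
        raise ChemistryError(f"ecosystems missing from chemistry: {sorted(missing)}")
    parts = [topology, chem.loc[topology.index]]
    if diversity is not None:
        missing = topology.index.difference(diversity.index)
        if len(missing):
            raise ChemistryError(f"ecosystems missing from diversity: {sorted(missing)}")
        parts.append(diversity.loc[topology.index])
    merged = pd.concat(parts, axis=1)
    merged = merged.loc[:, ~merged.columns.duplicated()]
    wanted = [f for f in features if f in merged.columns]
    absent = sorted(set(features) - set(wanted))
    if absent:
        raise ChemistryError(f"requested features not available: {absent}")
    return merged[wanted]


@dataclass
class PcaResult:
    """Ordination output: ratios, orthonormal loadings, ecosystem scores."""

    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # ecosystems x components
    standardized: bool


class TopologyChemistryPCA(BaseEstimator, TransformerMixin):
    """PCA of the ecosystem x feature matrix (z-scored by default).

    Columns are standardised (mean 0, unit variance, ddof=1) unless
    ``standardize=False``, then decomposed by full SVD. The sign of each
    component is fixed so that its largest-magnitude loading is positive,
    making outputs comparable across runs. Fitted attributes:
    ``explained_variance_ratio_``, ``loadings_`` (variables x components,
    orthonormal columns), ``scores_`` (rows x components), ``mean_``,
    ``scale_``.
    """

    def __init__(self, n_components: int | None = None, standardize: bool = True):
        self.n_components = n_components
        self.standardize = standardize

    def _check(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        if X.shape[0] < 3 or X.shape[1] < 2:
            raise ChemistryError(f"need >= 3 rows and >= 2 columns, got {X.shape}")
        if X.isna().to_numpy().any():
            cells = [(str(i), str(c)) for i, c in zip(*np.nonzero(X.isna().to_numpy()))]
            raise ChemistryError(f"missing values at (row, column) positions: {cells}")
        return X

    def fit(self, X, y=None):
        X = self._check(X)
        values = X.to_numpy(dtype=float)
        self.mean_ = values.mean(axis=0)
        if self.standardize:
            self.scale_ = values.std(axis=0, ddof=1)
            dead = self.scale_ == 0
            if dead.any():
                names = list(X.columns[dead])
                raise ChemistryError(f"constant column(s) cannot be standardised: {names}")
        else:
            self.scale_ = np.ones_like(self.mean_)
        Z = (values - self.mean_) / self.scale_

        n_comp = self.n_components or min(Z.shape[0] - 1, Z.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full")
        scores = pca.fit_transform(Z)
        components = pca.components_  # (n_comp, n_features)
        # deterministic sign: largest-|.| loading of each component positive
        flip = np.sign(components[np.arange(n_comp), np.abs(components).argmax(axis=1)])
        components = components * flip[:, None]
        scores = scores * flip[None, :]

        comp_names = [f"PC{i + 1}" for i in range(n_comp)]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.loadings_ = pd.DataFrame(components.T, index=X.columns, columns=comp_names)
        self.scores_ = pd.DataFrame(scores, index=X.index, columns=comp_names)
        return self

    def transform(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        Z = (X.to_numpy(dtype=float) - self.mean_) / self.scale_
        return pd.DataFrame(Z @ self.loadings_.to_numpy(), index=X.index,
                            columns=self.loadings_.columns)

    def result(self) -> PcaResult:
        return PcaResult(
            explained_variance_ratio=self.explained_variance_ratio_,
            loadings=self.loadings_,
            scores=self.scores_,
            standardized=self.standardize,
        )


def topology_chemistry_pca(
    features: pd.DataFrame, standardize: bool = True, n_components: int | None = None
) -> PcaResult:
    """Functional wrapper over :class:`TopologyChemistryPCA`."""
    est = TopologyChemistryPCA(n_components=n_components, standardize=standardize)
    return est.fit(features).result()


def write_pca(result: PcaResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.Series(
        result.explained_variance_ratio,
        index=[f"PC{i + 1}" for i in range(len(result.explained_variance_ratio))],
        name="explained_variance_ratio",
    ).to_csv(outdir / "explained_variance.csv")
    result.loadings.to_csv(outdir / "loadings.csv")
    result.scores.to_csv(outdir / "scores.csv")
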