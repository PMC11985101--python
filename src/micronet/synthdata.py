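"""Synthetic ASV tables with planted co-occurrence structure, plus chemistry.

The generator uses a Gaussian copula: ASVs are assigned round-robin to K
modules, a block latent correlation matrix is built (``module_rho`` inside a
block, ``background_rho`` between blocks), latent multivariate-normal
vectors are drawn per sample, and each ASV's latent value is pushed through
a monotone log-normal marginal whose per-ASV scale (the expected proportion)
is itself log-normal with sigma ``abundance_shape`` — a few dominant ASVs,
many rare ones, as in real amplicon surveys. Per-sample counts are then a
single multinomial draw at fixed sequencing depth, so columns sum exactly
to the depth.

Because Spearman correlation is invariant to monotone marginals, the
counted data inherit the planted rank structure up to the multinomial
discretisation and the compositional closure of the per-sample
normalisation: within a module the large-sample Spearman approaches the
bivariate-normal identity rho_S = (6/pi) * arcsin(rho/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import CHEMISTRY_TRAITS, ECOSYSTEMS, sampling_design, soil_chemistry
from .tables import AbundanceTable


class SpecError(ValueError):
    """Raised for invalid synthetic-ecosystem specifications."""


#: Within-ASV log-normal dispersion of the monotone marginal (natural-log
#: units). One log-unit of sample-to-sample variation is typical of
#: amplicon count tables; it only sets the signal-to-multinomial-noise
#: ratio, not the planted rank structure.
SAMPLE_SIGMA = 1.0


@dataclass(frozen=True)
class EcosystemSpec:
    """Parameters of one synthetic ecosystem.

    Attributes
    ----------
    name : ecosystem label.
    n_samples : number of samples (columns); >= 4.
    n_bacterial_asvs, n_fungal_asvs : ASVs per domain; bacterial ids come first.
    n_modules : number K of planted co-occurrence modules (>= 1, each gets >= 2 ASVs).
    module_rho : latent within-module correlation, in [0, 1).
    background_rho : latent between-module correlation, 0 <= background_rho <= module_rho.
    depth : sequencing depth (reads per sample).
    abundance_shape : log-normal sigma of per-ASV mean abundances (dominance).
    seed : RNG seed; identical spec + seed gives bit-identical tables.
    """

    name: str = "ecosystem"
    n_samples: int = 30
    n_bacterial_asvs: int = 150
    n_fungal_asvs: int = 50
    n_modules: int = 4
    module_rho: float = 0.85
    background_rho: float = 0.0
    depth: int = 50_000
    abundance_shape: float = 1.5
    seed: int = 0

    @property
    def n_asvs(self) -> int:
        return self.n_bacterial_asvs + self.n_fungal_asvs

    def validate(self) -> None:
        if self.n_samples < 4:
            raise SpecError(f"n_samples must be >= 4, got {self.n_samples}")
        if self.n_modules < 1:
            raise SpecError(f"n_modules must be >= 1, got {self.n_modules}")
        if self.n_asvs < 2 * self.n_modules:
            raise SpecError(
                f"{self.n_asvs} ASVs cannot give every one of "
                f"{self.n_modules} modules >= 2 members"
            )
        if not (0 <= self.background_rho <= self.module_rho < 1):
            raise SpecError(
                "latent correlations must satisfy 0 <= background_rho "
                f"<= module_rho < 1; got background_rho={self.background_rho}, "
                f"module_rho={self.module_rho} (non-PSD or ill-ordered pair)"
            )
        if self.depth <= 0:
            raise SpecError(f"depth must be positive, got {self.depth}")
        if self.abundance_shape < 0:
            raise SpecError(f"abundance_shape must be >= 0, got {self.abundance_shape}")


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic table."""

    module_label: pd.Series  # asv_id -> module id in [0, K)
    latent_correlation: np.ndarray  # symmetric PSD, ASV order = table order

    def __post_init__(self) -> None:
        n = len(self.module_label)
        if self.latent_correlation.shape != (n, n):
            raise SpecError("latent correlation shape does not match labels")

    def to_tsv(self, path: str | Path, domain: pd.Series) -> None:
        out = pd.DataFrame(
            {"domain": domain, "module_label": self.module_label}
        )
        out.index.name = "asv_id"
        out.to_csv(path, sep="\t")


def _block_correlation(labels: np.ndarray, module_rho: float, background_rho: float) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    corr = np.where(same, module_rho, background_rho).astype(float)
    np.fill_diagonal(corr, 1.0)
    # Block structure with 0 <= bg <= rho < 1 is PSD by construction, but a
    # cheap eigen check guards refactors and future parameterisations.
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise SpecError(
            f"latent correlation matrix not PSD for module_rho={module_rho}, "
            f"background_rho={background_rho}"
        )
    return corr


def generate_asv_table(spec: EcosystemSpec) -> tuple[AbundanceTable, GroundTruth]:
    """Draw one ecosystem's ASV count table with planted modules.

    Returns the count table (ASVs x samples, columns summing exactly to
    ``spec.depth``) and the ground-truth module labels plus latent
    correlation matrix.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p, n = spec.n_asvs, spec.n_samples

    labels = np.arange(p) % spec.n_modules  # round-robin module assignment
    corr = _block_correlation(labels, spec.module_rho, spec.background_rho)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(p))
    latent = rng.standard_normal((n, p)) @ chol.T

    mean_abund = rng.lognormal(mean=0.0, sigma=spec.abundance_shape, size=p)
    expected_props = mean_abund / mean_abund.sum()
    intensity = expected_props * np.exp(SAMPLE_SIGMA * latent)  # monotone in latent
    probs = intensity / intensity.sum(axis=1, keepdims=True)
    counts = rng.multinomial(spec.depth, probs)  # (n_samples, n_asvs)

    asv_ids = [
        f"{spec.name}_B{i:04d}" if i < spec.n_bacterial_asvs else f"{spec.name}_F{i:04d}"
        for i in range(p)
    ]
    domain = pd.Series(
        ["bacteria"] * spec.n_bacterial_asvs + ["fungi"] * spec.n_fungal_asvs,
        index=asv_ids, name="domain",
    )
    sample_ids = [f"{spec.name}_s{j:03d}" for j in range(n)]
    table = AbundanceTable(
        pd.DataFrame(counts.T, index=asv_ids, columns=sample_ids),
        domain=domain,
        ecosystem=pd.Series(spec.name, index=sample_ids, name="ecosystem"),
    )
    truth = GroundTruth(
        module_label=pd.Series(labels, index=asv_ids, name="module_label"),
        latent_correlation=corr,
    )
    return table, truth


def generate_taxonomy(table: AbundanceTable, truth: GroundTruth, seed: int = 0) -> pd.DataFrame:
    """Assign plausible six-rank lineages to synthetic ASVs.

    Phyla are drawn per domain from the groups that dominate soil
    co-occurrence networks (Proteobacteria, Actinobacteria, Bacteroidetes,
    Chloroflexi, Acidobacteria for bacteria; Ascomycota, Basidiomycota,
    Mortierellomycota for fungi); lower ranks are synthetic placeholders.
    """
    rng = np.random.default_rng(seed)
    bact = ["Proteobacteria", "Actinobacteria", "Bacteroidetes", "Chloroflexi", "Acidobacteria"]
    fung = ["Ascomycota", "Basidiomycota", "Mortierellomycota"]
    bact_w = np.array([0.35, 0.25, 0.15, 0.15, 0.10])
    fung_w = np.array([0.6, 0.3, 0.1])
    rows = {}
    for asv in table.asv_ids:
        if table.domain[asv] == "bacteria":
            kingdom, phylum = "Bacteria", rng.choice(bact, p=bact_w)
        else:
            kingdom, phylum = "Fungi", rng.choice(fung, p=fung_w)
        rows[asv] = {
            "kingdom": kingdom,
            "phylum": phylum,
            "class": f"{phylum}_class",
            "order": "unclassified",
            "family": f"fam{rng.integers(100):02d}",
            "genus": "unclassified",
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def generate_chemistry(
    specs: Sequence[EcosystemSpec],
    means: pd.DataFrame | None = None,
    cv: float = 0.1,
    n_replicates: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-replicate soil chemistry records around ecosystem means.

    Each trait is drawn from a normal truncated to its physical range
    (pH in [3, 10], everything else non-negative) with standard deviation
    ``cv * mean``; ``cv=0`` reproduces the means exactly. ``means`` defaults
    to the built-in reference chemistry; its rows are matched to the spec
    names, falling back to the reference ecosystems cyclically when a spec
    name is unknown.
    """
    if cv < 0:
        raise SpecError(f"cv must be >= 0, got {cv}")
    ref = soil_chemistry() if means is None else means
    if "CN" not in ref.columns:
        ref = ref.assign(CN=ref["OC"] / ref["TN"])
    if ((ref["pH"] < 3) | (ref["pH"] > 10)).any():
        raise SpecError("mean pH outside the physical range [3, 10]")
    others = [c for c in ref.columns if c != "pH"]
    if (ref[others] < 0).to_numpy().any():
        raise SpecError("mass/charge trait means must be non-negative")

    rng = np.random.default_rng(seed)
    records = []
    for i, spec in enumerate(specs):
        row = ref.loc[spec.name] if spec.name in ref.index else ref.iloc[i % len(ref)]
        for rep in range(n_replicates):
            rec = {"ecosystem": spec.name, "replicate": rep}
            for trait in ref.columns:
                mu = float(row[trait])
                lo, hi = (3.0, 10.0) if trait == "pH" else (0.0, np.inf)
                if cv == 0 or mu == 0:
                    val = mu
                else:
                    sd = cv * abs(mu)
                    a, b = (lo - mu) / sd, (hi - mu) / sd
                    val = float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
                rec[trait] = val
            # texture fractions are compositional: rescale the noisy triple
            # back to the ecosystem's total so sand+loam+clay stays <= 1000
            texture = [t for t in ("sand", "loam", "clay") if t in ref.columns]
            if len(texture) == 3:
                target = float(sum(row[t] for t in texture))
                drawn = sum(rec[t] for t in texture)
                if drawn > 0:
                    for t in texture:
                        rec[t] *= target / drawn
            rec["CN"] = rec["OC"] / rec["TN"] if rec["TN"] > 0 else np.nan
            records.append(rec)
    df = pd.DataFrame.from_records(records)
    cols = ["ecosystem", "replicate"] + [c for c in CHEMISTRY_TRAITS if c in df.columns]
    return df[cols]


def default_study_specs(
    seed: int = 0,
    n_bacterial_asvs: int = 150,
    n_fungal_asvs: int = 50,
    n_modules: int = 4,
    module_rho: float = 0.85,
) -> list[EcosystemSpec]:
    """Twelve ecosystem specs matching the reference survey's sample counts.

    Per-ecosystem sample sizes follow the field design (6-36 samples per
    ecosystem, 242 in total); every other parameter is shared. Seeds are
    derived deterministically from ``seed``.
    """
    design = sampling_design()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(ECOSYSTEMS))]
    return [
        EcosystemSpec(
            name=eco,
            n_samples=int(design[eco]),
            n_bacterial_asvs=n_bacterial_asvs,
            n_fungal_asvs=n_fungal_asvs,
            n_modules=n_modules,
            module_rho=module_rho,
            seed=child_seeds[i],
        )
        for i, eco in enumerate(ECOSYSTEMS)
    ]


def with_seed(spec: EcosystemSpec, seed: int) -> EcosystemSpec:
    """Copy of ``spec`` with a different RNG seed."""
    return replace(spec, seed=seed)
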