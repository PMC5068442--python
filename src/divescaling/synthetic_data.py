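"""Synthetic phylogenies and dive datasets with known ground truth.

The statistical model under test says that log dive duration is affine in log
body mass and temperature, with three nested sources of spread around that
plane: a phylogenetically correlated species deviation (Brownian motion on a
tree), an independent species deviation (repeated measures of the same
species share it), and independent residual noise.  This module generates
data with exactly that structure so that the fitters can be checked against a
known truth:

    ln t = beta0 + beta_mass * ln M + beta_temp * T
           + u_phylo(species) + u_species(species) + eps

Masses are drawn log-uniformly (default 10 g – 10^6 g, the amphibian-to-whale
span), temperatures uniformly (default 5–35 °C, an ectotherm-like range).
Everything is deterministic given the single seed stored in the truth object;
per-component substreams are derived from it so the tree, the random effects
and the noise can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data_prep import DiveDataset
from .phylo import Phylogeny, bm_covariance, read_newick

__all__ = [
    "SimTruth",
    "SyntheticDataset",
    "simulate_yule_tree",
    "simulate_phylo_effects",
    "simulate_dataset",
    "DEFAULT_MASS_RANGE",
    "DEFAULT_TEMP_RANGE",
]

DEFAULT_MASS_RANGE = (10.0, 1e6)
DEFAULT_TEMP_RANGE = (5.0, 35.0)

#: synthetic maximum dive duration = median x this factor (the two responses
#: are fitted separately, so their joint distribution is irrelevant here)
MAX_OVER_MEDIAN = 2.0

# substream tags for deriving independent generators from one seed
_STREAM_TREE, _STREAM_PHYLO, _STREAM_SPECIES, _STREAM_RECORDS = range(4)


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters of one simulated dataset (ln-minute scale)."""

    beta0: float = 3.0
    beta_mass: float = 0.25
    beta_temp: float = -0.12
    sigma2_phylo: float = 0.09
    sigma2_species: float = 0.04
    sigma2_resid: float = 0.09
    n_species: int = 200
    records_per_species: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be at least 2")
        if self.records_per_species < 1:
            raise ValueError("records_per_species must be at least 1")
        for name in ("sigma2_phylo", "sigma2_species", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        return cls(**json.loads(text))


class SyntheticDataset(NamedTuple):
    """Bundle returned by :func:`simulate_dataset`."""

    dataset: DiveDataset
    tree: Phylogeny
    truth: SimTruth
    phylo_effects: np.ndarray
    species_effects: np.ndarray


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _species_labels(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"sp{i + 1:0{width}d}" for i in range(n)]


def simulate_yule_tree(n_species: int, seed: int) -> Phylogeny:
    """A random pure-birth (Yule) tree with ``n_species`` extant tips.

    Starting from a single lineage, each lineage splits at rate 1; waiting
    times between events are exponential with mean ``1/k`` for ``k`` live
    lineages.  After the last split the tree is grown for one more waiting
    time so no tip sits exactly at a node.  The result is ultrametric, binary,
    with tips labeled ``sp001 ... spNNN``; identical seeds give identical
    newick strings.
    """
    if n_species < 2:
        raise ValueError("a Yule tree needs at least 2 species")
    rng = _rng(seed, _STREAM_TREE)

    class _Node:
        __slots__ = ("length", "label", "children")

        def __init__(self):
            self.length = 0.0
            self.label = None
            self.children = None

    root = _Node()
    active = [root]
    while len(active) < n_species:
        k = len(active)
        dt = rng.exponential(1.0 / k)
        for node in active:
            node.length += dt
        idx = int(rng.integers(k))
        parent = active[idx]
        left, right = _Node(), _Node()
        parent.children = (left, right)
        active[idx] = left
        active.append(right)
    dt = rng.exponential(1.0 / n_species)
    for node in active:
        node.length += dt

    for label, node in zip(_species_labels(n_species), active):
        node.label = label

    def render(node: _Node) -> str:
        if node.children is None:
            return f"{node.label}:{node.length:.12g}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{node.length:.12g}"

    # the time the stem lineage waited before its first split is shared by
    # every tip and thus confounded with the intercept; drop the root edge
    inner = ",".join(render(c) for c in root.children)
    return read_newick(f"({inner});")


def simulate_phylo_effects(
    tree: Phylogeny, sigma2_phylo: float, seed: int
) -> pd.Series:
    """Species deviations under Brownian motion on ``tree``.

    Draws one multivariate-normal vector with covariance
    ``sigma2_phylo * C`` where ``C`` is the unit-diagonal Brownian-motion
    matrix of the tree, indexed by tip label.  ``sigma2_phylo = 0`` gives
    exact zeros.
    """
    if sigma2_phylo < 0:
        raise ValueError("sigma2_phylo must be nonnegative")
    cov = bm_covariance(tree, normalize=True)
    n = len(cov.labels)
    if sigma2_phylo == 0:
        return pd.Series(np.zeros(n), index=list(cov.labels))
    rng = _rng(seed, _STREAM_PHYLO)
    jitter = 1e-10 * np.eye(n)
    chol = np.linalg.cholesky(sigma2_phylo * cov.matrix + jitter)
    draw = chol @ rng.standard_normal(n)
    return pd.Series(draw, index=list(cov.labels))


def simulate_dataset(
    truth: SimTruth,
    mass_range: tuple[float, float] = DEFAULT_MASS_RANGE,
    temp_range: tuple[float, float] = DEFAULT_TEMP_RANGE,
    taxon_class: str = "reptile",
) -> SyntheticDataset:
    """Simulate a dive dataset with the mixed-model structure of the analysis.

    For each of ``truth.n_species`` species on a fresh Yule tree,
    ``truth.records_per_species`` records are generated with ln(mass) uniform
    on ``ln(mass_range)`` and temperature uniform on ``temp_range``; the log
    median duration is the true plane plus phylogenetic, species and residual
    noise.  The synthetic maximum duration column is a fixed multiple
    (x2) of the median.  Deterministic given ``truth.seed``.
    """
    lo_m, hi_m = mass_range
    lo_t, hi_t = temp_range
    if not (0 < lo_m < hi_m) or not (lo_t < hi_t):
        raise ValueError("mass_range must be positive-increasing, temp_range increasing")

    tree = simulate_yule_tree(truth.n_species, truth.seed)
    u_phylo = simulate_phylo_effects(tree, truth.sigma2_phylo, truth.seed)

    rng_sp = _rng(truth.seed, _STREAM_SPECIES)
    labels = list(tree.tip_labels)
    u_species = pd.Series(
        np.sqrt(truth.sigma2_species) * rng_sp.standard_normal(len(labels)),
        index=labels,
    )

    rng = _rng(truth.seed, _STREAM_RECORDS)
    n_total = truth.n_species * truth.records_per_species
    ln_mass = rng.uniform(np.log(lo_m), np.log(hi_m), size=n_total)
    temp = rng.uniform(lo_t, hi_t, size=n_total)
    eps = np.sqrt(truth.sigma2_resid) * rng.standard_normal(n_total)

    species = np.repeat(labels, truth.records_per_species)
    ln_dur = (
        truth.beta0
        + truth.beta_mass * ln_mass
        + truth.beta_temp * temp
        + u_phylo.loc[species].to_numpy()
        + u_species.loc[species].to_numpy()
        + eps
    )
    median = np.exp(ln_dur)
    frame = pd.DataFrame(
        {
            "species": species,
            "genus": [s.split("_")[0] for s in species],
            "taxon_class": taxon_class,
            "group": "ectotherm" if taxon_class in ("reptile", "amphibian")
                     else "endotherm",
            "mass_g": np.exp(ln_mass),
            "temp_C": temp,
            "temp_source": "ambient_proxy",
            "median_dive_min": median,
            "max_dive_min": median * MAX_OVER_MEDIAN,
            "life_stage_sex": pd.NA,
        }
    )
    ds = DiveDataset(
        frame=frame,
        provenance=(
            {
                "step": "simulate_dataset",
                "before": 0,
                "after": n_total,
                "seed": truth.seed,
                "synthetic_max": f"median x {MAX_OVER_MEDIAN}",
            },
        ),
    )
    return SyntheticDataset(
        dataset=ds,
        tree=tree,
        truth=truth,
        phylo_effects=u_phylo.to_numpy(),
        species_effects=u_species.to_numpy(),
    )
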