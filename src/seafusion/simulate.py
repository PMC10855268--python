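"""Synthetic paired-design multi-omics and OTU data with planted structure.

Every downstream stage (pair centering, MFA, BE-PLS-DA, differential
abundance) is tested against data whose ground truth is known. The
generator emulates the study conditions: 6 day-pairs per exposure time,
continuous feature blocks on a log-intensity scale with an additive day
batch effect shared exactly by each day's control/treated pair, a sparse
planted treatment effect, and overdispersed OTU counts with library sizes
around the 10,000-read depth used for comparison.

Model for a continuous feature value::

    x[sample, j] = mu_j + delta_day(day, j) + planted effect + noise

where ``mu_j`` is a log-normal feature mean, ``delta_day ~ N(0, day_effect_sd)``
is common to both members of the pair, the planted effect is
``sign_j * effect_size * noise_sd`` added to treated samples only, and the
noise is Gaussian. OTU counts are negative binomial with mean
``library_size * proportion * 2**log2fc`` for planted taxa in the targeted
group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignError, validate_design
from .preprocess import OmicsBlock

#: block sizes per site, mirroring the numbers of identified molecules
SITE_BLOCK_SIZES: dict[str, dict[str, int]] = {
    "muscle": {"lipidomics": 921, "metabolomics": 464, "proteomics": 66},
    "skin": {"lipidomics": 944, "metabolomics": 384, "proteomics": 99},
    "gills": {"metabolomics": 380, "proteomics": 108},
    "eye": {"metabolomics": 340},
}

_BLOCK_PREFIX = {"lipidomics": "lip", "metabolomics": "met",
                 "proteomics": "pro"}


class SimulationError(ValueError):
    """Raised for invalid synthetic-data specifications."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the continuous-block generator.

    ``effect_size`` is a standardized mean shift on the within-day (noise)
    scale; ``day_effect_sd`` controls the additive batch effect removed by
    pair centering. ``distinct_time_effects`` plants disjoint feature sets
    for the 3 h and 24 h treated groups so that the four classes separate
    in unsupervised analyses.
    """

    n_days_per_time: int = 6
    block_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(SITE_BLOCK_SIZES["muscle"]))
    n_planted: int = 20
    effect_size: float = 3.0
    day_effect_sd: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    distinct_time_effects: bool = False

    def __post_init__(self) -> None:
        if self.day_effect_sd < 0 or self.noise_sd < 0:
            raise SimulationError("standard deviations must be >= 0")
        for name, p in self.block_sizes.items():
            if p <= 0:
                raise SimulationError(f"block {name!r} has size {p}")
            if self.n_planted > p:
                raise SimulationError(
                    f"n_planted={self.n_planted} exceeds block {name!r} "
                    f"size {p}")


@dataclass(frozen=True)
class PlantedFeature:
    block: str
    index: int
    feature_id: str
    effect: float
    #: None = planted in both time points, else "t3h"/"t24h"
    time: str | None = None


@dataclass(frozen=True)
class PlantedTaxon:
    index: int
    taxon_id: str
    log2fc: float


@dataclass(frozen=True)
class PlantedTruth:
    """Immutable record of the planted signal."""

    features: tuple[PlantedFeature, ...] = ()
    taxa: tuple[PlantedTaxon, ...] = ()

    def feature_ids(self, block: str | None = None,
                    time: str | None = None) -> list[str]:
        out = []
        for f in self.features:
            if block is not None and f.block != block:
                continue
            if time is not None and f.time is not None and f.time != time:
                continue
            out.append(f.feature_id)
        return out


def feature_ids_for(block_name: str, size: int) -> list[str]:
    prefix = _BLOCK_PREFIX.get(block_name, block_name[:3])
    return [f"{prefix}_{i:04d}" for i in range(size)]


def generate_multiomics(
        design: pd.DataFrame, spec: SyntheticSpec,
        rng: np.random.Generator | None = None,
) -> tuple[dict[str, OmicsBlock], PlantedTruth]:
    """Simulate continuous omics blocks for a single-site paired design.

    Returns the blocks keyed by name plus the planted truth. Identical
    ``spec`` (including seed) and design give byte-identical output.
    """
    validate_design(design)
    sites = set(design["site"])
    if len(sites) != 1:
        raise SimulationError(
            f"generate_multiomics expects a single-site design, got {sorted(sites)};"
            " generate each site separately")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = len(design)
    days = design["day"].to_numpy()
    treated = (design["group"] == "treated").to_numpy()
    times = design["time"].to_numpy()
    uniq_days = np.unique(days)

    blocks: dict[str, OmicsBlock] = {}
    planted: list[PlantedFeature] = []
    for name in sorted(spec.block_sizes):
        p = int(spec.block_sizes[name])
        fids = feature_ids_for(name, p)
        mu = rng.lognormal(mean=2.0, sigma=0.5, size=p)
        day_eff = rng.normal(0.0, spec.day_effect_sd, size=(len(uniq_days), p))
        day_row = {d: i for i, d in enumerate(uniq_days)}
        x = np.tile(mu, (n, 1))
        for i, d in enumerate(days):
            x[i] += day_eff[day_row[d]]

        scopes: Sequence[str | None]
        if spec.distinct_time_effects:
            scopes = ("t3h", "t24h")
        else:
            scopes = (None,)
        taken: set[int] = set()
        for scope in scopes:
            avail = np.setdiff1d(np.arange(p), sorted(taken))
            if spec.n_planted > len(avail):
                raise SimulationError(
                    f"not enough features in block {name!r} for disjoint "
                    "planted sets per time point")
            idx = rng.choice(avail, size=spec.n_planted, replace=False)
            signs = rng.choice([-1.0, 1.0], size=spec.n_planted)
            taken.update(int(i) for i in idx)
            effects = signs * spec.effect_size * spec.noise_sd
            rows = treated if scope is None else treated & (times == scope)
            x[np.ix_(rows, idx)] += effects
            planted.extend(
                PlantedFeature(block=name, index=int(j), feature_id=fids[j],
                               effect=float(e), time=scope)
                for j, e in zip(idx, effects))
        x += rng.normal(0.0, spec.noise_sd, size=(n, p))
        blocks[name] = OmicsBlock(
            name=name,
            data=pd.DataFrame(x, index=design["sample_id"].to_numpy(),
                              columns=fids))
    return blocks, PlantedTruth(features=tuple(planted))


@dataclass
class OTUTable:
    """Taxa-by-samples integer counts with taxonomy labels."""

    counts: pd.DataFrame  # taxa (index) x samples (columns)
    taxonomy: pd.Series  # taxon id -> family-level label

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be non-negative")
        self.taxonomy = self.taxonomy.reindex(self.counts.index)

    @property
    def library_size(self) -> pd.Series:
        return self.counts.sum(axis=0)


def generate_otu_counts(
        design: pd.DataFrame,
        n_taxa: int = 58,
        mean_abundances: np.ndarray | Sequence[float] | None = None,
        dispersion: float = 0.1,
        planted_log2fc: Mapping[int, float] | None = None,
        seed: int | np.random.Generator = 0,
        target_group: str = "treated",
        target_time: str | None = None,
        libsize_meanlog: float = math.log(1e4),
        libsize_sdlog: float = 0.3,
) -> tuple[OTUTable, PlantedTruth]:
    """Simulate an overdispersed OTU count table for a paired design.

    Counts are negative binomial with per-taxon mean
    ``library_size * proportion``, multiplied by ``2**log2fc`` for planted
    taxa in the targeted group (optionally restricted to one time point).
    ``dispersion`` is the NB dispersion (variance = m + dispersion * m^2);
    0 gives Poisson counts. Library sizes are log-normal around 10^4 reads.
    """
    validate_design(design)
    if dispersion < 0:
        raise SimulationError("dispersion must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if mean_abundances is None:
        raw = rng.lognormal(mean=0.0, sigma=1.5, size=n_taxa)
        props = raw / raw.sum()
    else:
        props = np.asarray(mean_abundances, dtype=float)
        if len(props) != n_taxa:
            raise SimulationError("mean_abundances length != n_taxa")
        if (props <= 0).any():
            raise SimulationError("abundances must be > 0")
        props = props / props.sum()
    planted_log2fc = dict(planted_log2fc or {})
    for idx in planted_log2fc:
        if not 0 <= idx < n_taxa:
            raise SimulationError(f"planted taxon index {idx} out of range "
                                  f"for n_taxa={n_taxa}")

    taxa = [f"Family{i + 1:03d}" for i in range(n_taxa)]
    samples = design["sample_id"].to_numpy()
    in_scope = (design["group"] == target_group).to_numpy()
    if target_time is not None:
        in_scope &= (design["time"] == target_time).to_numpy()

    lib = rng.lognormal(mean=libsize_meanlog, sigma=libsize_sdlog,
                        size=len(samples))
    fc = np.ones(n_taxa)
    counts = np.zeros((n_taxa, len(samples)), dtype=np.int64)
    for s in range(len(samples)):
        mult = fc.copy()
        if in_scope[s]:
            for idx, lfc in planted_log2fc.items():
                mult[idx] = 2.0 ** lfc
        mean = lib[s] * props * mult
        if dispersion == 0:
            counts[:, s] = rng.poisson(mean)
        else:
            r = 1.0 / dispersion
            counts[:, s] = rng.negative_binomial(r, r / (r + mean))
    table = OTUTable(
        counts=pd.DataFrame(counts, index=taxa, columns=samples),
        taxonomy=pd.Series(taxa, index=taxa, name="family"))
    truth = PlantedTruth(taxa=tuple(
        PlantedTaxon(index=i, taxon_id=taxa[i], log2fc=float(l))
        for i, l in sorted(planted_log2fc.items())))
    return table, truth


def spawn_rng(seed: int, stage: int) -> np.random.Generator:
    """Derive a stage generator from the master seed (documented rule:
    ``SeedSequence(seed, spawn_key=(stage,))``)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def respec(spec: SyntheticSpec, **kw) -> SyntheticSpec:
    """Convenience: a copy of ``spec`` with fields replaced."""
    return replace(spec, **kw)
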