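"""Synthetic knee-OA cohorts and external validation tables.

The study data this pipeline targets (a 51-woman moderate-OA cohort with
seven ordinal clinical descriptors, a 25-patient synovial-fluid subset with
eleven Luminex analytes, and a large external WOMAC table) are access
restricted, so every downstream stage is developed and tested against
synthetic cohorts that reproduce the statistical structure the analysis
assumes:

* ordinal descriptors obtained by discretizing a Gaussian latent trait at
  fixed *population* quantile cuts (so a planted cut is a well-defined
  object to recover);
* positive, right-skewed analyte concentrations (log-normal);
* planted monotone feature -> descriptor associations of configurable
  effect size, either linear in the standardized feature or a step shift
  between its low/high halves;
* an OAI-like wide table with correlated feature blocks, WOMAC-style
  left/right targets, surgery-history flags and cell-level missingness.

Reproducibility: one global seed expands into independent per-stream child
seeds via ``numpy.random.SeedSequence([seed, blake2s(stream_name)])``, so a
column's values do not depend on the order in which columns are generated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ANALYTE_NAMES",
    "DEFAULT_DESCRIPTORS",
    "DescriptorSpec",
    "PlantedEffect",
    "CohortConfig",
    "CohortTable",
    "ConfigurationError",
    "generate_cohort",
    "generate_external_table",
    "EXTERNAL_TARGETS",
]

#: Synovial-fluid analytes measured by the multiplex immunoassay panel.
ANALYTE_NAMES = (
    "IL-6", "IL-8", "IL-4", "TNFa", "IL-18", "IFNg",
    "IL-17", "IL-1RA", "MCP1", "VEGF-A", "LEPTIN",
)

#: WOMAC-style targets of the external validation table (Left/Right knee
#: pain, functionality, rigidity), on the cohort descriptors' scales.
EXTERNAL_TARGETS = (
    "WOMAC_pain_L", "WOMAC_pain_R",
    "WOMAC_function_L", "WOMAC_function_R",
    "WOMAC_rigidity_L", "WOMAC_rigidity_R",
)

# number of MC draws used to locate population quantile cuts
_POPULATION_SIZE = 200_000
_POPULATION_SEED = 20240523  # fixed: cuts are population constants, not per-run draws


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


def _stream_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Child seed for a named stream; independent of column generation order."""
    key = int.from_bytes(hashlib.blake2s(name.encode(), digest_size=4).digest(), "big")
    return np.random.SeedSequence([int(seed), key])


def _stream_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(_stream_seed(seed, name))


@dataclass(frozen=True)
class DescriptorSpec:
    """One ordinal clinical descriptor.

    Single-item descriptors (``n_items == 1``) take values ``0..levels-1``.
    Multi-item questionnaire scores sum ``n_items`` Likert items, each on
    ``0..item_levels-1``, giving a ``0..n_items*(item_levels-1)`` range.
    """

    name: str
    levels: int = 4
    n_items: int = 1
    item_levels: int = 5

    def __post_init__(self):
        if self.levels < 2 or self.item_levels < 2 or self.n_items < 1:
            raise ConfigurationError(f"descriptor {self.name!r}: ordinal levels must be >= 2")

    @property
    def value_range(self) -> tuple[int, int]:
        if self.n_items == 1:
            return (0, self.levels - 1)
        return (0, self.n_items * (self.item_levels - 1))


#: The seven descriptors of the cohort: WOMAC joint pain (5 Likert items),
#: WOMAC functionality (17 items), WOMAC rigidity (2 items), central
#: sensitization grade, HAD depression score, pain-catastrophizing score,
#: echographic synovitis grade.
DEFAULT_DESCRIPTORS = (
    DescriptorSpec("JP", n_items=5, item_levels=5),
    DescriptorSpec("FU", n_items=17, item_levels=5),
    DescriptorSpec("RI", n_items=2, item_levels=5),
    DescriptorSpec("SE", levels=4),
    DescriptorSpec("DE", levels=22),
    DescriptorSpec("CA", levels=53),
    DescriptorSpec("SY", levels=4),
)


@dataclass(frozen=True)
class PlantedEffect:
    """A monotone association planted from a feature onto a descriptor.

    ``effect`` is expressed in units of the descriptor's latent noise SD.
    ``kind="linear"`` adds ``effect * z`` to the latent (z the standardized
    feature); ``kind="step"`` adds ``effect * 1{z > 0}``, i.e. a latent
    shift between the low and high halves of the feature — the step places
    a single recoverable cut at the latent mixture's median, whereas a
    linear effect makes every quantile cut equally discriminable.
    """

    feature: str
    descriptor: str
    effect: float
    direction: int = 1
    kind: str = "linear"

    def __post_init__(self):
        if self.direction not in (1, -1):
            raise ConfigurationError("direction must be +1 or -1")
        if self.kind not in ("linear", "step"):
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        if self.effect < 0:
            raise ConfigurationError("effect size must be >= 0 (use direction=-1)")


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 51
    n_sf_subset: int = 25
    descriptor_specs: tuple[DescriptorSpec, ...] = DEFAULT_DESCRIPTORS
    analyte_names: tuple[str, ...] = ANALYTE_NAMES
    planted_effects: tuple[PlantedEffect, ...] = ()
    noise_sd: float = 1.0
    analyte_meanlog: float = 1.0
    analyte_sdlog: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")
        if not (0 <= self.n_sf_subset <= self.n_subjects):
            raise ConfigurationError("n_sf_subset must be <= n_subjects")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        names = [d.name for d in self.descriptor_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate descriptor names")
        if len(set(self.analyte_names)) != len(self.analyte_names):
            raise ConfigurationError("duplicate analyte names")
        known = set(names) | set(self.analyte_names)
        order = {n: i for i, n in enumerate(names)}
        for eff in self.planted_effects:
            if eff.descriptor not in order:
                raise ConfigurationError(f"planted effect targets unknown descriptor {eff.descriptor!r}")
            if eff.feature not in known:
                raise ConfigurationError(f"planted effect uses unknown feature {eff.feature!r}")
            if eff.feature in order and order[eff.feature] >= order[eff.descriptor]:
                raise ConfigurationError(
                    f"planted effect {eff.feature!r}->{eff.descriptor!r}: a descriptor "
                    "feature must precede its target in descriptor_specs"
                )


@dataclass
class CohortTable:
    """Subjects x features with per-feature kind tags and ordinal ranges.

    ``data`` is a DataFrame indexed by unique subject ids; ``kinds`` maps
    each column to ``clinical | analyte | tf | admin``; ``ordinal_ranges``
    gives the declared (lo, hi) range of every clinical column. Missing
    values are NaN.
    """

    data: pd.DataFrame
    kinds: dict = field(default_factory=dict)
    ordinal_ranges: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicated subject ids")
        for col, kind in self.kinds.items():
            if col not in self.data.columns:
                raise ValueError(f"kind declared for missing column {col!r}")
            vals = self.data[col].dropna().to_numpy()
            if kind == "clinical" and col in self.ordinal_ranges:
                lo, hi = self.ordinal_ranges[col]
                if len(vals) and (not np.allclose(vals, np.round(vals)) or vals.min() < lo or vals.max() > hi):
                    raise ValueError(f"clinical column {col!r} leaves ordinal range [{lo}, {hi}]")
            if kind == "analyte" and len(vals) and vals.min() <= 0:
                raise ValueError(f"analyte column {col!r} has non-positive values")

    def columns_of_kind(self, kind: str) -> list:
        return [c for c in self.data.columns if self.kinds.get(c) == kind]

    def to_csv(self, path, sidecar=None) -> None:
        self.data.to_csv(path, index_label="subject_id", lineterminator="\n")
        if sidecar is not None:
            meta = {
                "kinds": dict(self.kinds),
                "ordinal_ranges": {k: list(v) for k, v in self.ordinal_ranges.items()},
            }
            with open(sidecar, "w") as fh:
                yaml.safe_dump(meta, fh, sort_keys=True)

    @classmethod
    def from_csv(cls, path, sidecar=None) -> "CohortTable":
        df = pd.read_csv(path, index_col="subject_id")
        kinds, ranges = {}, {}
        if sidecar is not None:
            with open(sidecar) as fh:
                meta = yaml.safe_load(fh)
            kinds = meta.get("kinds", {})
            ranges = {k: tuple(v) for k, v in meta.get("ordinal_ranges", {}).items()}
        return cls(df, kinds, ranges)


def _quantile_cuts(population: np.ndarray, n_levels: int) -> np.ndarray:
    probs = np.arange(1, n_levels) / n_levels
    return np.quantile(population, probs)


def _standardized_features(config: CohortConfig, rng_for, size: int) -> dict:
    """Standard-normal driver per analyte name (shared by value and latent)."""
    return {name: rng_for(f"analyte:{name}").standard_normal(size) for name in config.analyte_names}


def _descriptor_latents(config: CohortConfig, std_features: dict, rng_for, size: int) -> dict:
    """Latent trait per descriptor, in config order so descriptor features resolve."""
    latents: dict = {}
    for spec in config.descriptor_specs:
        latent = config.noise_sd * rng_for(f"descriptor:{spec.name}:noise").standard_normal(size)
        for eff in config.planted_effects:
            if eff.descriptor != spec.name:
                continue
            if eff.feature in std_features:
                z = std_features[eff.feature]
            else:
                prior = latents[eff.feature]
                z = prior / max(prior.std(), 1e-12)
            g = z if eff.kind == "linear" else (z > 0).astype(float)
            latent = latent + eff.direction * eff.effect * config.noise_sd * g
        latents[spec.name] = latent
    return latents


def _discretize_descriptor(spec: DescriptorSpec, latent: np.ndarray, pop_latent: np.ndarray,
                           rng_for, noise_sd: float) -> np.ndarray:
    if spec.n_items == 1:
        cuts = _quantile_cuts(pop_latent, spec.levels)
        return np.searchsorted(cuts, latent).astype(int)
    # multi-item: each Likert item is the latent plus item-specific noise,
    # discretized at the item population's quantile cuts, then summed
    pop_rng = np.random.default_rng(_POPULATION_SEED + 1)
    total = np.zeros(len(latent), dtype=int)
    for item in range(spec.n_items):
        item_pop = pop_latent + noise_sd * pop_rng.standard_normal(len(pop_latent))
        cuts = _quantile_cuts(item_pop, spec.item_levels)
        item_noise = noise_sd * rng_for(f"descriptor:{spec.name}:item{item}").standard_normal(len(latent))
        total += np.searchsorted(cuts, latent + item_noise).astype(int)
    return total


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Generate a synthetic cohort table. Deterministic given ``config.seed``.

    Clinical descriptor columns hold ordinal integers in their declared
    ranges for all subjects; analyte columns are positive (log-normal) and
    non-missing only for the first ``n_sf_subset`` subjects (the
    effusion/synovial-fluid subset).
    """
    n = config.n_subjects
    rng_for = lambda name: _stream_rng(config.seed, name)

    std = _standardized_features(config, rng_for, n)
    latents = _descriptor_latents(config, std, rng_for, n)

    # population draws (fixed internal seed) to place the quantile cuts
    pop_rng_for = lambda name: _stream_rng(_POPULATION_SEED, name)
    pop_std = _standardized_features(config, pop_rng_for, _POPULATION_SIZE)
    pop_latents = _descriptor_latents(config, pop_std, pop_rng_for, _POPULATION_SIZE)

    subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    cols, kinds, ranges = {}, {}, {}
    for spec in config.descriptor_specs:
        vals = _discretize_descriptor(spec, latents[spec.name], pop_latents[spec.name],
                                      rng_for, config.noise_sd)
        cols[spec.name] = vals.astype(float)
        kinds[spec.name] = "clinical"
        ranges[spec.name] = spec.value_range
    sf_mask = np.arange(n) < config.n_sf_subset
    for name in config.analyte_names:
        vals = np.exp(config.analyte_meanlog + config.analyte_sdlog * std[name])
        vals = np.where(sf_mask, vals, np.nan)
        cols[name] = vals
        kinds[name] = "analyte"

    df = pd.DataFrame(cols, index=pd.Index(subject_ids, name="subject_id"))
    return CohortTable(df, kinds, ranges)


def planted_cut(config: CohortConfig, descriptor: str) -> float:
    """Ordinal-scale threshold corresponding to a planted step split.

    For a single-item descriptor driven by one step effect, the recoverable
    cut is the population-median quantile cut; this returns the midpoint
    threshold on the ordinal scale (e.g. 1.5 for a 4-level descriptor).
    """
    spec = next(d for d in config.descriptor_specs if d.name == descriptor)
    if spec.n_items != 1:
        raise ValueError("planted_cut is defined for single-item descriptors")
    if spec.levels % 2:
        raise ValueError("even number of levels required for a median cut")
    return spec.levels / 2 - 0.5


def generate_external_table(
    n_rows: int,
    n_features: int = 300,
    missing_rate: float = 0.0,
    n_surgery: int = 0,
    seed: int = 0,
    block_size: int = 4,
    block_rho: float = 0.6,
    n_informative: int = 8,
    effect: float = 3.0,
    target_noise_sd: float = 1.0,
) -> CohortTable:
    """OAI-like wide validation table. Deterministic given ``seed``.

    Features come in equicorrelated blocks of ``block_size`` (pairwise
    correlation ``block_rho``). Six WOMAC-style targets (left/right pain,
    functionality, rigidity, on the cohort descriptor scales 0-20 / 0-68 /
    0-8) are driven by ``n_informative`` features per subscale with total
    signal ``effect`` latent-noise SDs; left and right knees share the
    informative set but have independent noise. A binary
    ``surgery_history`` flag marks ``n_surgery`` rows; feature cells are
    masked missing independently at ``missing_rate``.
    """
    if n_surgery > n_rows:
        raise ConfigurationError("n_surgery must be <= n_rows")
    if not (0 <= missing_rate < 1):
        raise ConfigurationError("missing_rate must be in [0, 1)")
    if n_features < 3 * n_informative:
        raise ConfigurationError("n_features too small for the informative subsets")

    def draw_features(rng, size):
        X = np.empty((size, n_features))
        for j0 in range(0, n_features, block_size):
            width = min(block_size, n_features - j0)
            g = rng.standard_normal(size)
            eps = rng.standard_normal((size, width))
            X[:, j0:j0 + width] = np.sqrt(block_rho) * g[:, None] + np.sqrt(1 - block_rho) * eps
        return X

    target_specs = {  # subscale -> (ordinal levels of the summed score)
        "pain": 21, "function": 69, "rigidity": 9,
    }
    # disjoint informative sets, one block-aligned slice per subscale
    informative = {
        sub: list(range(i * n_informative, (i + 1) * n_informative))
        for i, sub in enumerate(target_specs)
    }

    def draw_targets(rng, X):
        out = {}
        for sub, levels in target_specs.items():
            idx = informative[sub]
            signal = (effect * target_noise_sd / np.sqrt(len(idx))) * X[:, idx].sum(axis=1)
            for side in ("L", "R"):
                out[f"WOMAC_{sub}_{side}"] = signal + target_noise_sd * rng.standard_normal(len(X))
        return out

    rng = _stream_rng(seed, "external:data")
    X = draw_features(rng, n_rows)
    latents = draw_targets(_stream_rng(seed, "external:targets"), X)

    pop_rng = np.random.default_rng(_POPULATION_SEED + 10)
    Xp = draw_features(pop_rng, 50_000)
    pop_latents = draw_targets(np.random.default_rng(_POPULATION_SEED + 11), Xp)

    cols, kinds, ranges = {}, {}, {}
    feat_names = [f"V{j + 1:03d}" for j in range(n_features)]
    miss_rng = _stream_rng(seed, "external:missing")
    for j, name in enumerate(feat_names):
        vals = X[:, j].copy()
        if missing_rate > 0:
            vals[miss_rng.random(n_rows) < missing_rate] = np.nan
        cols[name] = vals
        kinds[name] = "clinical"
    for sub, levels in target_specs.items():
        for side in ("L", "R"):
            name = f"WOMAC_{sub}_{side}"
            cuts = _quantile_cuts(pop_latents[name], levels)
            cols[name] = np.searchsorted(cuts, latents[name]).astype(float)
            kinds[name] = "clinical"
            ranges[name] = (0, levels - 1)
    flag = np.zeros(n_rows)
    if n_surgery:
        pick = _stream_rng(seed, "external:surgery").choice(n_rows, size=n_surgery, replace=False)
        flag[pick] = 1.0
    cols["surgery_history"] = flag
    kinds["surgery_history"] = "admin"

    ids = [f"P{i + 1:05d}" for i in range(n_rows)]
    df = pd.DataFrame(cols, index=pd.Index(ids, name="subject_id"))
    return CohortTable(df, kinds, ranges)
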