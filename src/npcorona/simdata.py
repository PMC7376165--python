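"""Generative model of plasma, nanoparticle corona formation and MS readout.

The simulator provides ground-truth inputs for every analysis stage:

* a plasma proteome with log-uniform concentrations spanning a configurable
  number of orders of magnitude (default 10, the span of the circulating
  plasma proteome);
* engineered nanoparticles with log-normal, annotation-biased binding
  affinities, so that the coronas of different particles are distinct but
  partially overlapping;
* corona formation by single-site competitive Langmuir adsorption,
  B_ij = S_j · a_ij C_i / (1 + Σ_k a_kj C_k), which normalizes measured
  abundance by binding affinity and, combined with a finite surface
  capacity and a detection limit, compresses the measured dynamic range;
* a label-free MS observation model: multiplicative log-normal replicate
  noise plus logistic intensity-dependent dropout at the limit of
  detection, with missing values coded explicitly (never zero);
* spike-in series and contamination scenarios (platelet signature,
  hemolysate, lipid interference).

All randomness flows from a single master seed; per-stage generators are
derived with ``numpy.random.default_rng([seed, offset, ...])`` so every
output is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .matrixio import COLUMN_LEVELS, AnnotationCatalog, IntensityTensor

#: the six assay conditions screened per particle: the standard assay plus
#: five variants of particle load, plasma dilution and buffer system.
DEFAULT_CONDITIONS = (
    "standard",
    "low_particle",
    "plasma_dilute",
    "plasma_neat",
    "citrate_low",
    "citrate_high",
)

ANNOTATION_SPACES = ("GOCC", "GOBP", "Keywords", "Pfam", "KEGG")


# ---------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------

@dataclass
class PlasmaProteome:
    """Ground-truth plasma composition.

    ``concentration`` holds the true per-protein concentration C_i
    (arbitrary mass/volume units, strictly positive); ``annotations`` maps
    annotation-space labels to catalogs of term→member sets;
    ``is_platelet_signature`` flags the planted platelet-contamination
    signature; ``spike_factor`` records applied spike multipliers.
    """

    protein_ids: np.ndarray
    concentration: np.ndarray
    annotations: dict[str, AnnotationCatalog] = field(default_factory=dict)
    is_platelet_signature: np.ndarray | None = None
    spike_factor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.protein_ids = np.asarray(self.protein_ids, dtype=object)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if len(self.protein_ids) != len(self.concentration):
            raise ValueError("protein_ids and concentration lengths differ")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("protein IDs must be unique")
        if np.any(~(self.concentration > 0)):
            raise ValueError("all concentrations must be strictly positive")
        n = len(self.protein_ids)
        if self.is_platelet_signature is None:
            self.is_platelet_signature = np.zeros(n, dtype=bool)
        if self.spike_factor is None:
            self.spike_factor = np.ones(n, dtype=float)
        self.is_platelet_signature = np.asarray(self.is_platelet_signature, dtype=bool)
        self.spike_factor = np.asarray(self.spike_factor, dtype=float)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def index_of(self, protein_id: str) -> int:
        hits = np.flatnonzero(self.protein_ids == protein_id)
        if len(hits) == 0:
            raise KeyError(f"unknown protein {protein_id!r}")
        return int(hits[0])

    @property
    def platelet_signature_ids(self) -> frozenset:
        return frozenset(self.protein_ids[self.is_platelet_signature])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration": self.concentration,
                "platelet_signature": self.is_platelet_signature,
                "spike_factor": self.spike_factor,
            },
            index=pd.Index(self.protein_ids, name="protein_id"),
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


@dataclass
class AffinitySpec:
    """Parameters of the per-particle affinity model.

    Affinities are log-normal: log10 a_ij ~ Normal(log10_mean, log10_sd)
    per particle, with members of ``n_bias_terms`` randomly chosen
    annotation terms multiplied by ``bias_factor`` (particle-specific
    surface chemistry favoring a protein class). Inverse-concentration
    units: a·C ≫ 1 saturates the surface, a·C ≪ 1 is the linear regime.
    """

    log10_mean: float = -6.0
    log10_sd: float = 1.0
    n_bias_terms: int = 2
    bias_factor: float = 5.0
    bias_space: str | None = None  # None: draw terms from any space


@dataclass
class NanoparticleModel:
    """One engineered particle: affinity vector a_ij aligned to the proteome,
    total surface capacity S_j (mass units), replicate noise CV, and the
    logistic detection-limit midpoint/slope on the log10-intensity axis."""

    np_id: str
    affinity: np.ndarray
    capacity: float = 1.0
    noise_cv: float = 0.22
    lod_mid: float = 4.0
    lod_slope: float = 1.5

    def __post_init__(self) -> None:
        self.affinity = np.asarray(self.affinity, dtype=float)
        if np.any(self.affinity < 0):
            raise ValueError("affinities must be nonnegative")
        if not self.capacity > 0:
            raise ValueError("capacity must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if not self.lod_slope > 0:
            raise ValueError("lod_slope must be positive")

    def restrict(self, mask: np.ndarray) -> "NanoparticleModel":
        """Particle model aligned to a subset proteome (see subset_proteome)."""
        return replace(self, affinity=self.affinity[np.asarray(mask)])


@dataclass
class CoronaComposition:
    """Deterministic adsorption outcome: bound amount B_ij per protein."""

    np_id: str
    protein_ids: np.ndarray
    bound_amount: np.ndarray

    def __post_init__(self) -> None:
        self.bound_amount = np.asarray(self.bound_amount, dtype=float)
        if np.any(self.bound_amount < 0):
            raise ValueError("bound amounts must be nonnegative")

    @property
    def total_bound(self) -> float:
        return float(self.bound_amount.sum())


@dataclass
class AssayDesign:
    """Replicate and condition structure of one assay run."""

    n_replicates: int = 3
    conditions: tuple = DEFAULT_CONDITIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")


# ---------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------

def default_annotation_plan(n_proteins: int, rng: np.random.Generator,
                            n_terms_per_space: int = 20) -> dict:
    """Term-size plan: five annotation spaces, term sizes log-uniform
    between 8 and n/10 (annotation sizes in real catalogs are heavy-tailed)."""
    hi = max(12, n_proteins // 10)
    plan: dict[str, dict[str, int]] = {}
    for space in ANNOTATION_SPACES:
        sizes = np.exp(rng.uniform(np.log(8), np.log(hi), size=n_terms_per_space))
        plan[space] = {
            f"{space}:{k:04d}": int(round(s)) for k, s in enumerate(sizes)
        }
    return plan


def generate_plasma_proteome(
    n_proteins: int,
    dynamic_range_orders: float = 10.0,
    seed: int = 0,
    annotation_spec: dict | None = None,
    platelet_fraction: float = 0.02,
    base_concentration: float = 1.0,
) -> PlasmaProteome:
    """Draw a plasma proteome with log-uniform concentrations.

    After rescaling, the empirical log10-concentration range equals
    ``dynamic_range_orders`` exactly. ``annotation_spec`` maps annotation
    space → {term: size}; members are drawn uniformly without replacement
    per term (terms may overlap). A ``platelet_fraction`` of proteins is
    flagged as the platelet contamination signature.
    """
    if n_proteins < 2:
        raise ValueError("n_proteins must be >= 2")
    if not dynamic_range_orders > 0:
        raise ValueError("dynamic_range_orders must be positive")
    rng = np.random.default_rng([seed, 1])
    u = rng.uniform(0.0, 1.0, size=n_proteins)
    span = u.max() - u.min()
    log10_c = (u - u.min()) / span * dynamic_range_orders
    concentration = base_concentration * 10.0 ** log10_c
    ids = np.array([f"P{i:05d}" for i in range(n_proteins)], dtype=object)

    if annotation_spec is None:
        annotation_spec = default_annotation_plan(n_proteins, rng)
    annotations = {}
    for space, terms in annotation_spec.items():
        catalog_terms = {}
        descriptions = {}
        for term, size in terms.items():
            size = min(int(size), n_proteins)
            members = rng.choice(ids, size=size, replace=False)
            catalog_terms[term] = frozenset(members)
            descriptions[term] = f"synthetic {space} term"
        annotations[space] = AnnotationCatalog(space, catalog_terms, descriptions)

    n_sig = int(round(platelet_fraction * n_proteins))
    signature = np.zeros(n_proteins, dtype=bool)
    if n_sig:
        signature[rng.choice(n_proteins, size=n_sig, replace=False)] = True

    return PlasmaProteome(ids, concentration, annotations, signature)


def generate_nanoparticles(
    proteome: PlasmaProteome,
    n_nps: int,
    seed: int = 0,
    affinity_spec: AffinitySpec | None = None,
    capacity: float = 1.0,
    noise_cv: float = 0.22,
    lod_mid: float = 4.0,
    lod_slope: float = 1.5,
) -> list[NanoparticleModel]:
    """Draw ``n_nps`` particle models with independent, annotation-biased
    log-normal affinity vectors (distinct but overlapping coronas)."""
    if proteome.n_proteins == 0:
        raise ValueError("empty proteome")
    if n_nps < 1:
        raise ValueError("n_nps must be >= 1")
    spec = affinity_spec or AffinitySpec()
    id_to_idx = {p: i for i, p in enumerate(proteome.protein_ids)}
    all_terms = []
    for space, catalog in proteome.annotations.items():
        if spec.bias_space is None or space == spec.bias_space:
            all_terms.extend((space, term) for term in catalog.terms)
    models = []
    for j in range(n_nps):
        rng = np.random.default_rng([seed, 2, j])
        log10_a = spec.log10_mean + spec.log10_sd * rng.standard_normal(proteome.n_proteins)
        affinity = 10.0 ** log10_a
        if spec.n_bias_terms > 0 and all_terms:
            k = min(spec.n_bias_terms, len(all_terms))
            chosen = rng.choice(len(all_terms), size=k, replace=False)
            for t in chosen:
                space, term = all_terms[int(t)]
                members = proteome.annotations[space].terms[term]
                idx = [id_to_idx[m] for m in members if m in id_to_idx]
                affinity[idx] *= spec.bias_factor
        models.append(
            NanoparticleModel(
                np_id=f"NP-{j + 1:03d}",
                affinity=affinity,
                capacity=capacity,
                noise_cv=noise_cv,
                lod_mid=lod_mid,
                lod_slope=lod_slope,
            )
        )
    return models


def neat_plasma_particle(
    proteome: PlasmaProteome,
    noise_cv: float = 0.22,
    lod_mid: float = 4.0,
    lod_slope: float = 1.5,
    capacity: float = 1.0,
) -> NanoparticleModel:
    """Pseudo-particle for a neat-plasma measurement: uniform affinity in the
    saturated regime, so measured amounts are proportional to true
    concentration (B ∝ C/ΣC) with the same noise and detection model."""
    affinity = np.full(proteome.n_proteins, 1e3 / proteome.concentration.sum())
    return NanoparticleModel(
        np_id="plasma", affinity=affinity, capacity=capacity,
        noise_cv=noise_cv, lod_mid=lod_mid, lod_slope=lod_slope,
    )


def form_corona(proteome: PlasmaProteome, np_model: NanoparticleModel) -> CoronaComposition:
    """Competitive single-site Langmuir adsorption:
    B_ij = S_j · a_ij C_i / (1 + Σ_k a_kj C_k). Total bound mass never
    exceeds the capacity S_j, and zero-affinity proteins bind nothing."""
    if len(np_model.affinity) != proteome.n_proteins:
        raise ValueError(
            f"affinity vector of {np_model.np_id} has length "
            f"{len(np_model.affinity)}, proteome has {proteome.n_proteins}"
        )
    ac = np_model.affinity * proteome.concentration
    bound = np_model.capacity * ac / (1.0 + ac.sum())
    return CoronaComposition(np_model.np_id, proteome.protein_ids.copy(), bound)


@lru_cache(maxsize=None)
def _calibrated_sigma(noise_cv: float, n_replicates: int) -> float:
    """Log-normal σ such that the *median n-replicate sample CV* — the
    statistic assay precision is reported as — equals the nominal CV.

    The CV identity σ = sqrt(ln(1+cv²)) targets the distributional CV; the
    sample CV of few replicates is biased low (its median is ≈0.83·cv at
    n=3), so σ is inflated by solving median-CV(σ) = cv on a fixed
    quasi-Monte-Carlo draw (secant iteration; deterministic, independent of
    user seeds)."""
    if noise_cv == 0:
        return 0.0
    sigma0 = float(np.sqrt(np.log1p(noise_cv ** 2)))
    if n_replicates < 2:
        return sigma0
    z = np.random.default_rng(987654321).standard_normal((50_000, n_replicates))

    def median_cv(sigma: float) -> float:
        x = np.exp(sigma * z)
        return float(np.median(x.std(axis=1, ddof=1) / x.mean(axis=1)))

    df = n_replicates - 1
    a = sigma0
    b = sigma0 / float(np.sqrt(chi2.ppf(0.5, df) / df))  # normal-approx start
    fa, fb = median_cv(a) - noise_cv, median_cv(b) - noise_cv
    for _ in range(20):
        if fb == fa:
            break
        c = b - fb * (b - a) / (fb - fa)
        a, fa = b, fb
        b, fb = c, median_cv(c) - noise_cv
        if abs(fb) < 1e-4 * noise_cv:
            break
    return float(b)


def observe_ms(
    corona: CoronaComposition,
    np_model: NanoparticleModel,
    design: AssayDesign,
    seed: int = 0,
    intensity_scale: float = 1e12,
    condition_effects: dict | None = None,
    sample_id: str = "pool",
) -> IntensityTensor:
    """Simulate label-free MS readout of one corona.

    Per replicate: intensity = scale · effect_c · B_ij · LogNormal(σ) with
    σ = sqrt(ln(1+cv²)) corrected for small-replicate sample-CV bias; each
    value is then independently censored with probability
    1 − logistic((log10 I − lod_mid) · lod_slope). Missing is NaN in the
    tensor (written as ``NA``), never zero. ``condition_effects`` maps
    condition label → multiplicative loading factor (default 1).
    """
    rng = np.random.default_rng([seed, 3])
    sigma = _calibrated_sigma(float(np_model.noise_cv), design.n_replicates)
    effects = condition_effects or {}
    n = len(corona.bound_amount)
    blocks = {}
    for condition in design.conditions:
        eff = float(effects.get(condition, 1.0))
        base = intensity_scale * eff * corona.bound_amount
        for rep in range(1, design.n_replicates + 1):
            noise = np.exp(sigma * rng.standard_normal(n)) if sigma > 0 else 1.0
            intensity = base * noise
            with np.errstate(divide="ignore"):
                log_i = np.where(intensity > 0, np.log10(np.where(intensity > 0, intensity, 1.0)), -np.inf)
            arg = (log_i - np_model.lod_mid) * np_model.lod_slope
            # lod_mid = ±inf short-circuits to all-present / all-missing
            if np.isneginf(np_model.lod_mid):
                p_obs = np.where(np.isfinite(log_i), 1.0, 0.0)
            elif np.isposinf(np_model.lod_mid):
                p_obs = np.zeros(n)
            else:
                p_obs = expit(arg)
            observed = rng.uniform(size=n) < p_obs
            values = np.where(observed & (intensity > 0), intensity, np.nan)
            blocks[(np_model.np_id, condition, sample_id, rep)] = values
    columns = pd.MultiIndex.from_tuples(blocks.keys(), names=COLUMN_LEVELS)
    frame = pd.DataFrame(
        np.column_stack(list(blocks.values())),
        index=pd.Index(corona.protein_ids, name="protein_id"),
        columns=columns,
    )
    return IntensityTensor(frame)


def simulate_screen(
    proteome: PlasmaProteome,
    particles: list[NanoparticleModel],
    design: AssayDesign | None = None,
    seed: int = 0,
    intensity_scale: float = 1e12,
    condition_effect_sd: float = 0.5,
    sample_id: str = "pool",
) -> IntensityTensor:
    """Full multi-particle, multi-condition screen of one pooled sample.

    Condition effects (assay loading differences) are drawn per
    (particle, condition) as 10**Normal(0, condition_effect_sd), the
    ``standard`` condition pinned at 1, so detected counts genuinely vary
    across conditions.
    """
    design = design or AssayDesign()
    pieces = []
    for j, np_model in enumerate(particles):
        rng = np.random.default_rng([seed, 4, j])
        effects = {
            c: 1.0 if c == "standard" else 10.0 ** (condition_effect_sd * rng.standard_normal())
            for c in design.conditions
        }
        corona = form_corona(proteome, np_model)
        tensor = observe_ms(
            corona, np_model, design, seed=seed * 1000 + j,
            intensity_scale=intensity_scale, condition_effects=effects,
            sample_id=sample_id,
        )
        pieces.append(tensor.data)
    return IntensityTensor(pd.concat(pieces, axis=1))


# ---------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------

def apply_spike(proteome: PlasmaProteome, protein_id: str,
                fold_levels: list[float]) -> list[PlasmaProteome]:
    """Spike series: one proteome per fold level with only the named
    protein's concentration multiplied (1× = unspiked control)."""
    idx = proteome.index_of(protein_id)
    out = []
    for fold in fold_levels:
        if not fold > 0:
            raise ValueError(f"spike fold must be positive, got {fold}")
        conc = proteome.concentration.copy()
        conc[idx] *= fold
        spike = proteome.spike_factor.copy()
        spike[idx] = fold
        out.append(
            PlasmaProteome(
                proteome.protein_ids.copy(), conc, proteome.annotations,
                proteome.is_platelet_signature.copy(), spike,
            )
        )
    return out


def apply_contamination(
    proteome: PlasmaProteome,
    mode: str,
    level: float,
    n_added_proteins: int = 30,
    added_orders: float = 3.0,
    seed: int = 0,
) -> PlasmaProteome:
    """Contamination scenarios.

    ``platelet``: multiply the planted signature proteins by (1+level).
    ``hemolysate``: append ``n_added_proteins`` new erythrocyte-lysate
    proteins at concentrations level·w_k, the fixed weights w_k log-spaced
    over ``added_orders`` orders (level 0 adds nothing).
    ``lipid``: non-proteinaceous interference — the protein content is
    returned unchanged (lipids add no protein IDs).
    """
    if level < 0:
        raise ValueError("level must be nonnegative")
    if mode == "lipid" or level == 0:
        if mode not in ("platelet", "hemolysate", "lipid"):
            raise ValueError(f"unknown contamination mode {mode!r}")
        return PlasmaProteome(
            proteome.protein_ids.copy(), proteome.concentration.copy(),
            proteome.annotations, proteome.is_platelet_signature.copy(),
            proteome.spike_factor.copy(),
        )
    if mode == "platelet":
        conc = proteome.concentration.copy()
        conc[proteome.is_platelet_signature] *= 1.0 + level
        return PlasmaProteome(
            proteome.protein_ids.copy(), conc, proteome.annotations,
            proteome.is_platelet_signature.copy(), proteome.spike_factor.copy(),
        )
    if mode == "hemolysate":
        weights = np.logspace(0.0, added_orders, n_added_proteins)
        new_ids = np.array([f"HEMO{i:04d}" for i in range(n_added_proteins)], dtype=object)
        ids = np.concatenate([proteome.protein_ids, new_ids])
        conc = np.concatenate([proteome.concentration, level * weights])
        sig = np.concatenate([proteome.is_platelet_signature,
                              np.zeros(n_added_proteins, dtype=bool)])
        spike = np.concatenate([proteome.spike_factor, np.ones(n_added_proteins)])
        return PlasmaProteome(ids, conc, proteome.annotations, sig, spike)
    raise ValueError(f"unknown contamination mode {mode!r}")


def subset_proteome(proteome: PlasmaProteome, mask: np.ndarray) -> PlasmaProteome:
    """Positional subset (e.g. the pre-contamination proteins of a
    hemolysate-spiked proteome); pair with NanoparticleModel.restrict."""
    mask = np.asarray(mask)
    return PlasmaProteome(
        proteome.protein_ids[mask], proteome.concentration[mask],
        proteome.annotations, proteome.is_platelet_signature[mask],
        proteome.spike_factor[mask],
    )
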