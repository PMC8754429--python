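"""Synthetic BRENDA/ProThermDB-like datasets with known ground truth.

Every pipeline stage is exercised against generated tables whose generating
process is fully known, so that statistical behaviour (null calibration,
power, parameter recovery) can be checked without any database download.

The kinetic generator draws, per reaction r and variant v at growth
temperature T_v:

    log10(k_v) = mu_r + beta * T_v + eps,   eps ~ Normal(0, sigma_noise)

with mu_r ~ Normal(0, sigma_reaction).  ``beta`` is the ground-truth
temperature slope: beta = 0 is the no-compensation null, beta < 0 encodes
rate compensation (cold-adapted variants faster).

Growth temperatures are drawn on a whole-degree grid with extra probability
mass on common culture temperatures (25/28/30/37 degC).  Curated
growth-temperature tables are reported at about this precision, and the
shared values are what make distinct organisms coincide in T_Growth --
without them the same-temperature control distribution would be empty.

Defaults correspond to a realistic literature-scale extract: 2223
multi-organism reactions spanning 1-83 degC for kinetics; 433 wild-type
records with 43 two-member families for stability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .mm import InitialRateSeries, michaelis_menten

__all__ = [
    "KineticSimConfig",
    "StabilitySimConfig",
    "generate_kinetic_dataset",
    "generate_same_temperature_variants",
    "generate_stability_dataset",
    "generate_mm_series",
]

# Distribution of enzyme variants per reaction: dominated by two-variant
# reactions with a long tail, as in literature-scale extracts where ~43% of
# multi-organism reactions have more than two variants.
_DEFAULT_VARIANT_DIST: Mapping[int, float] = {
    2: 0.57,
    3: 0.20,
    4: 0.10,
    5: 0.06,
    6: 0.04,
    8: 0.02,
    12: 0.01,
}

# Common culture temperatures and their relative weights within the
# "common" mixture component.
_COMMON_TEMPS: Mapping[float, float] = {25.0: 0.3, 28.0: 0.2, 30.0: 0.3, 37.0: 0.2}

# Fixed substream ids so adding a generator never perturbs existing streams.
_STREAMS = {
    "structure": 0,
    "temperatures": 1,
    "rates": 2,
    "injection": 3,
    "same_temperature": 4,
    "stability": 5,
    "mm": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class KineticSimConfig:
    """Generating process for a BRENDA-like kinetic extract.

    ``mutant_rate`` is the probability that a variant additionally emits a
    mutant-enzyme row; ``unmatched_rate`` the probability that a reaction
    gains an extra wild-type variant whose organism is absent from the
    growth-temperature table.  Both inject rows *on top of* the core design,
    so the curated output still matches the ground truth exactly.
    ``organism_reuse`` is the probability a variant reuses an organism
    already drawn for another reaction, exercising the organism-matching
    paths.
    """

    n_reactions: int = 2223
    variants_per_reaction: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_VARIANT_DIST)
    )
    t_growth_range_C: tuple[float, float] = (1.0, 83.0)
    beta: float = 0.0
    sigma_reaction: float = 1.2
    sigma_noise: float = 1.0
    replicate_rate: float = 0.15
    mutant_rate: float = 0.5
    unmatched_rate: float = 0.3
    organism_reuse: float = 0.5
    common_temp_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be positive")
        for name in ("replicate_rate", "mutant_rate", "unmatched_rate",
                     "organism_reuse", "common_temp_weight"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.sigma_reaction < 0 or self.sigma_noise < 0:
            raise ValueError("sigmas must be non-negative")
        lo, hi = self.t_growth_range_C
        if not lo < hi:
            raise ValueError("t_growth_range_C must be an increasing interval")
        probs = self.variants_per_reaction
        if not probs or any(m < 2 for m in probs) or any(p < 0 for p in probs.values()):
            raise ValueError("variants_per_reaction must map counts >= 2 to weights >= 0")


@dataclass(frozen=True)
class StabilitySimConfig:
    """Generating process for a ProThermDB-like wild-type T_m table.

    T_m = intercept_a + slope_b * T_Growth + Normal(0, sigma).  The first
    ``families_with_pairs`` protein families receive a cold- and a
    warm-adapted member (drawn from the lower and upper ~third of the
    temperature range, the spans literature family pairs actually cover);
    the remaining proteins are singletons.
    """

    n_proteins: int = 433
    families_with_pairs: int = 43
    slope_b: float = 0.35
    intercept_a: float = 45.0
    sigma: float = 10.0
    t_growth_range_C: tuple[float, float] = (1.0, 83.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if 2 * self.families_with_pairs > self.n_proteins:
            raise ValueError("family members cannot exceed n_proteins")


def _draw_t_growth(rng: np.random.Generator, config: KineticSimConfig) -> float:
    lo, hi = config.t_growth_range_C
    common = [t for t in _COMMON_TEMPS if lo <= t <= hi]
    if common and rng.random() < config.common_temp_weight:
        weights = np.array([_COMMON_TEMPS[t] for t in common])
        return float(rng.choice(common, p=weights / weights.sum()))
    return float(rng.integers(int(np.ceil(lo)), int(np.floor(hi)) + 1))


def _draw_variant_count(rng: np.random.Generator, dist: Mapping[int, float]) -> int:
    counts = sorted(dist)
    weights = np.array([dist[c] for c in counts], dtype=float)
    return int(rng.choice(counts, p=weights / weights.sum()))


_ASSAY_TEMPS = (25.0, 30.0, 37.0, None)
_ASSAY_WEIGHTS = (0.45, 0.15, 0.30, 0.10)


def generate_kinetic_dataset(
    config: KineticSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a kinetic-entry table, its growth-temperature table, and the
    ground truth.

    The entries table uses the ``SYNTHETIC_KINETIC`` dialect columns; the
    ground truth records every reaction's baseline, slope and variant-level
    true values, sufficient to recompute every generated rate.
    Deterministic given ``config.seed``.
    """
    rng_struct = _rng(config.seed, "structure")
    rng_temp = _rng(config.seed, "temperatures")
    rng_rate = _rng(config.seed, "rates")
    rng_inj = _rng(config.seed, "injection")

    pool: list[tuple[str, float]] = []  # (name, T_Growth) of matchable organisms
    n_unmatched_orgs = 0
    rows: list[dict] = []
    truth_reactions: list[dict] = []
    entry_counter = 0

    def emit(ec: str, substrate: str, organism: str, value: float,
             status: str, assay: Optional[float]) -> None:
        nonlocal entry_counter
        rows.append(
            {
                "entry_id": f"e{entry_counter:07d}",
                "ec_number": ec,
                "substrate": substrate,
                "organism": organism,
                "value": value,
                "value_type": "kcat",
                "variant_status": status,
                "assay_temperature_C": assay if assay is not None else "",
            }
        )
        entry_counter += 1

    for r in range(config.n_reactions):
        ec = (
            f"{rng_struct.integers(1, 7)}.{rng_struct.integers(1, 10)}."
            f"{rng_struct.integers(1, 10)}.{rng_struct.integers(1, 100)}"
        )
        substrate = f"substrate_{r:05d}"
        m = _draw_variant_count(rng_struct, config.variants_per_reaction)
        mu = float(rng_rate.normal(0.0, config.sigma_reaction))
        used: set[str] = set()
        variants = []
        for _ in range(m):
            candidates = [o for o in pool if o[0] not in used]
            if candidates and rng_struct.random() < config.organism_reuse:
                name, t_v = candidates[rng_struct.integers(0, len(candidates))]
            else:
                name = f"Synthetibacter variani{len(pool):05d}"
                t_v = _draw_t_growth(rng_temp, config)
                pool.append((name, t_v))
            used.add(name)

            n_meas = 1
            if rng_struct.random() < config.replicate_rate:
                n_meas = int(rng_struct.integers(2, 4))
            log_ks = mu + config.beta * t_v + rng_rate.normal(
                0.0, config.sigma_noise, size=n_meas
            )
            for log_k in log_ks:
                assay = rng_struct.choice(len(_ASSAY_TEMPS), p=_ASSAY_WEIGHTS)
                emit(ec, substrate, name, float(10.0**log_k), "wild_type",
                     _ASSAY_TEMPS[assay])
                if rng_inj.random() < config.mutant_rate:
                    mut_k = 10.0 ** (log_k + rng_inj.normal(0.0, 1.0))
                    emit(ec, substrate, name, float(mut_k), "mutant",
                         _ASSAY_TEMPS[assay])
            variants.append(
                {
                    "organism": name,
                    "t_growth_C": t_v,
                    "log10_k_true": float(mu + config.beta * t_v),
                    "n_measurements": n_meas,
                }
            )
        if rng_inj.random() < config.unmatched_rate:
            n_unmatched_orgs += 1
            stray = f"Ignotum absentis{n_unmatched_orgs:05d}"
            k = 10.0 ** float(rng_inj.normal(mu, 1.0))
            emit(ec, substrate, stray, k, "wild_type", None)
        truth_reactions.append(
            {
                "ec_number": ec,
                "substrate": substrate,
                "mu": mu,
                "beta": config.beta,
                "variants": variants,
            }
        )

    entries = pd.DataFrame(rows)
    t_table = pd.DataFrame(
        [{"organism": name, "t_growth_C": t} for name, t in pool]
    )
    truth = {
        "config": dataclasses.asdict(config),
        "n_organisms": len(pool),
        "reactions": truth_reactions,
    }
    return entries, t_table, truth


def generate_same_temperature_variants(
    config: KineticSimConfig,
    k_spread: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reactions whose variants all share one T_Growth (the control path).

    Each reaction's variant rates span exactly a factor ``k_spread``
    (log-evenly spaced), so the control fold-change pair of a two-variant
    reaction is (k_spread, 1/k_spread).  Returns the entries table and the
    matching growth-temperature table; no reaction has temperature spread,
    so the rate-ratio path yields nothing on this dataset.
    """
    if k_spread < 1:
        raise ValueError("k_spread must be >= 1")
    rng = _rng(config.seed, "same_temperature")
    rows = []
    t_rows = []
    org_counter = 0
    for r in range(config.n_reactions):
        ec = (
            f"{rng.integers(1, 7)}.{rng.integers(1, 10)}."
            f"{rng.integers(1, 10)}.{rng.integers(1, 100)}"
        )
        substrate = f"ctrl_substrate_{r:05d}"
        m = _draw_variant_count(rng, config.variants_per_reaction)
        t_shared = _draw_t_growth(rng, config)
        base = 10.0 ** float(rng.normal(0.0, config.sigma_reaction))
        ks = base * np.logspace(0.0, np.log10(k_spread), m) if k_spread > 1 else np.full(m, base)
        for k in ks:
            name = f"Isothermus communis{org_counter:05d}"
            org_counter += 1
            t_rows.append({"organism": name, "t_growth_C": t_shared})
            rows.append(
                {
                    "entry_id": f"c{len(rows):07d}",
                    "ec_number": ec,
                    "substrate": substrate,
                    "organism": name,
                    "value": float(k),
                    "value_type": "kcat",
                    "variant_status": "wild_type",
                    "assay_temperature_C": 25.0,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(t_rows)


def generate_stability_dataset(
    config: StabilitySimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a wild-type stability table, growth-temperature table and
    ground truth.

    Family pairs place their cold member in the lower ~third and their warm
    member in the upper ~third of the temperature range; singleton proteins
    draw uniformly over the whole range.
    """
    rng = _rng(config.seed, "stability")
    lo, hi = config.t_growth_range_C
    span = hi - lo
    rows = []
    t_rows = []
    truth_records = []
    org_counter = 0

    def add(protein: str, t_growth: float, family: Optional[str]) -> None:
        nonlocal org_counter
        organism = f"Stabilibacter firmus{org_counter:05d}"
        org_counter += 1
        t_m = config.intercept_a + config.slope_b * t_growth + float(
            rng.normal(0.0, config.sigma)
        )
        t_rows.append({"organism": organism, "t_growth_C": t_growth})
        rows.append(
            {
                "protein_name": protein,
                "organism": organism,
                "mutation": "wild-type",
                "t_m_C": t_m,
                "ph": 7.0,
                "method": "DSC",
                "state": "native",
                "reversibility": "yes",
            }
        )
        truth_records.append(
            {
                "protein_name": protein,
                "family": family,
                "organism": organism,
                "t_growth_C": t_growth,
                "t_m_true": config.intercept_a + config.slope_b * t_growth,
                "t_m_C": t_m,
            }
        )

    for f in range(config.families_with_pairs):
        family = f"family_{f:03d}"
        t_cold = float(rng.uniform(lo, lo + 0.35 * span))
        t_warm = float(rng.uniform(hi - 0.35 * span, hi))
        add(family, t_cold, family)
        add(family, t_warm, family)
    for p in range(config.n_proteins - 2 * config.families_with_pairs):
        add(f"protein_{p:04d}", float(rng.uniform(lo, hi)), None)

    truth = {"config": dataclasses.asdict(config), "records": truth_records}
    return pd.DataFrame(rows), pd.DataFrame(t_rows), truth


def generate_mm_series(
    k_cat: float,
    K_M: float,
    enzyme_conc_uM: float,
    substrate_concs_uM: Sequence[float] = (9.0, 25.0, 50.0, 100.0, 300.0, 600.0),
    noise_cv: float = 0.0,
    seed: int = 0,
    variant_label: str = "synthetic_variant",
    organism: str = "Synthetibacter variani00000",
    t_growth_C: Optional[float] = None,
) -> InitialRateSeries:
    """Initial-rate series from known Michaelis-Menten parameters.

    v_i = k_cat * E * S_i / (K_M + S_i) * (1 + Normal(0, noise_cv)),
    truncated away from zero.  Deterministic given ``seed``.
    """
    if min(k_cat, K_M, enzyme_conc_uM) <= 0:
        raise ValueError("k_cat, K_M and enzyme concentration must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = _rng(seed, "mm")
    s = np.asarray(substrate_concs_uM, dtype=float)
    v = michaelis_menten(s, k_cat, K_M, enzyme_conc_uM)
    v = v * (1.0 + rng.normal(0.0, noise_cv, size=s.size)) if noise_cv > 0 else v
    v = np.maximum(v, 1e-12 * float(np.max(v)))
    return InitialRateSeries(
        variant_label=variant_label,
        organism=organism,
        enzyme_conc_uM=float(enzyme_conc_uM),
        points=tuple(zip(s.tolist(), v.tolist())),
        t_growth_C=t_growth_C,
    )
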