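"""Synthetic longitudinal COPD cohort generator.

Emits cohorts with the statistical structure the analysis pipeline assumes,
together with per-sample ground truth, so every downstream stage can be
tested without access to the original sequencing data:

* per-patient visit sequences (1–13 visits; first visit stable, later
  visits exacerbations with fixed probability);
* a five-state Markov chain over joint inflammation x community states
  {NH, NB, E, MIXED, PAUCI} with separate stable->stable and
  stable->exacerbation transition matrices whose diagonal persistences
  default to the reported 0.714 / 0.384 / 0.418 (stable–stable) and
  0.591 / 0.214 / 0.333 (stable–exacerbation) for NH / NB / E;
* a four-type community structure (balanced, Haemophilus-, Moraxella- and
  Streptococcus-predominant) drawn from per-type Dirichlet concentration
  vectors over 24 named genera, emitted as multinomial read counts;
* endotype-conditioned sputum differential cell percentages (truncated
  normals per state, jointly renormalised when the five classes exceed
  100 %) and log-scale mediator panels (Th1/Th17/Th2 patterns per state);
* a latent eosinophilia coupling: the concentrations of eosinophil-tracking
  genera (Campylobacter, Granulicatella, and friends) are scaled by
  exp(coupling * z) where z is the sample's standardised eosinophil
  percentage, creating both cross-sectional enrichment in eosinophilic
  samples and within-patient temporal co-variation for the time-series
  modules to detect.

MIXED and PAUCI are generated even though the transition analysis uses only
NH/NB/E, so the exclusion rules downstream have something to exclude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .core_io import CohortDataset, GenusAbundanceTable, SampleMetadata

__all__ = [
    "STATES",
    "GENERA",
    "COMMUNITY_KINDS",
    "GeneratorConfig",
    "SyntheticTruth",
    "default_config",
    "sample_state_sequence",
    "sample_composition",
    "generate_cohort",
]

STATES = ("NH", "NB", "E", "MIXED", "PAUCI")
COMMUNITY_KINDS = ("balanced", "haemophilus", "moraxella", "streptococcus")

GENERA = (
    "Haemophilus", "Moraxella", "Streptococcus", "Veillonella", "Prevotella",
    "Campylobacter", "Granulicatella", "Gemellaceae", "Capnocytophaga",
    "Fusobacterium", "Rothia", "Porphyromonas", "Neisseria", "Actinomyces",
    "Leptotrichia", "Actinobacillus", "Serratia", "Oribacterium",
    "Lactobacillus", "Lautropia", "Mycoplasma", "Acinetobacter", "Gemella",
    "Treponema",
)

# ---------------------------------------------------------------------------
# default parameters


def _balanced_means() -> np.ndarray:
    """Mean composition of the 'balanced' community type.

    Veillonella + Prevotella carry a combined mean of 0.26 (the reported
    optimal cutoff for segregating the balanced subgroup); the top genus
    stays below the 0.3 dominance threshold.
    """
    named = {
        "Veillonella": 0.14, "Prevotella": 0.12, "Streptococcus": 0.06,
        "Neisseria": 0.05, "Rothia": 0.04, "Actinomyces": 0.04,
        "Haemophilus": 0.03, "Leptotrichia": 0.03, "Fusobacterium": 0.03,
        "Porphyromonas": 0.03, "Granulicatella": 0.02, "Campylobacter": 0.02,
        "Gemellaceae": 0.02, "Capnocytophaga": 0.02, "Gemella": 0.02,
    }
    rest = [g for g in GENERA if g not in named]
    fill = (1.0 - sum(named.values())) / len(rest)
    return np.array([named.get(g, fill) for g in GENERA])


def _dominated_means(genus: str, dominance: float) -> np.ndarray:
    """Dominated community mean: target genus mass + balanced-proportional rest."""
    base = _balanced_means()
    idx = GENERA.index(genus)
    rest = base.copy()
    rest[idx] = 0.0
    rest = rest / rest.sum() * (1.0 - dominance)
    rest[idx] = dominance
    return rest


def _default_concentrations() -> dict[str, np.ndarray]:
    return {
        "balanced": _balanced_means() * 100.0,
        "haemophilus": _dominated_means("Haemophilus", 0.60) * 150.0,
        "moraxella": _dominated_means("Moraxella", 0.60) * 150.0,
        "streptococcus": _dominated_means("Streptococcus", 0.60) * 150.0,
    }


# transition matrices: rows/cols ordered as STATES. Diagonals for NH/NB/E are
# the reported persistences; off-diagonal mass follows the qualitative
# pattern (NH and E nearly mutually exclusive, NB interchangeable with both).
# NH/NB/E leak only ~2 % into MIXED/PAUCI so that persistences measured
# after pair exclusion stay close to the configured diagonals; MIXED/PAUCI
# presence comes mainly from the initial distribution and their own rows.
_STABLE_STABLE = np.array(
    [
        [0.714, 0.250, 0.016, 0.010, 0.010],
        [0.200, 0.384, 0.396, 0.010, 0.010],
        [0.060, 0.502, 0.418, 0.010, 0.010],
        [0.060, 0.300, 0.200, 0.280, 0.160],
        [0.060, 0.270, 0.100, 0.120, 0.450],
    ]
)
_STABLE_EXAC = np.array(
    [
        [0.591, 0.350, 0.019, 0.020, 0.020],
        [0.476, 0.214, 0.270, 0.020, 0.020],
        [0.060, 0.547, 0.333, 0.030, 0.030],
        [0.100, 0.330, 0.200, 0.250, 0.120],
        [0.100, 0.330, 0.150, 0.120, 0.300],
    ]
)
_INITIAL = np.array([0.10, 0.30, 0.14, 0.18, 0.28])

# per-state mixture over community kinds (NH is Haemophilus-predominant and
# NB balanced by definition; the other states occasionally carry dominated
# communities so that all four types appear at roughly the reported cohort
# proportions ~70/15/7/6 %).
_COMMUNITY_MIX = {
    "NH": {"haemophilus": 1.0},
    "NB": {"balanced": 1.0},
    "E": {"balanced": 0.80, "moraxella": 0.10, "streptococcus": 0.10},
    "MIXED": {"balanced": 0.65, "haemophilus": 0.10, "moraxella": 0.12, "streptococcus": 0.13},
    "PAUCI": {"balanced": 0.62, "haemophilus": 0.08, "moraxella": 0.15, "streptococcus": 0.15},
}

# sputum differential cell percentages: (mean, sd) per state. NH/NB/E follow
# the reported subgroup moments; MIXED/PAUCI are design choices consistent
# with their defining thresholds.
_CELL_STATS = {
    "NH": {"neutrophil_pct": (88.8, 10.3), "eosinophil_pct": (0.6, 0.7), "lymphocyte_pct": (0.3, 1.0), "macrophage_pct": (6.3, 5.1), "epithelial_pct": (2.2, 3.6)},
    "NB": {"neutrophil_pct": (80.5, 11.3), "eosinophil_pct": (0.9, 0.9), "lymphocyte_pct": (0.5, 1.7), "macrophage_pct": (10.7, 8.2), "epithelial_pct": (3.6, 5.4)},
    "E": {"neutrophil_pct": (38.7, 21.1), "eosinophil_pct": (10.1, 11.7), "lymphocyte_pct": (0.4, 0.7), "macrophage_pct": (30.1, 18.4), "epithelial_pct": (6.0, 5.9)},
    "MIXED": {"neutrophil_pct": (75.0, 8.0), "eosinophil_pct": (6.0, 3.0), "lymphocyte_pct": (0.5, 0.8), "macrophage_pct": (12.0, 8.0), "epithelial_pct": (4.0, 5.0)},
    "PAUCI": {"neutrophil_pct": (45.0, 10.0), "eosinophil_pct": (1.2, 0.8), "lymphocyte_pct": (0.5, 0.8), "macrophage_pct": (40.0, 15.0), "epithelial_pct": (8.0, 6.0)},
}

# sputum mediators on log scale, (mean, sd) per NH/NB/E; MIXED/PAUCI use the
# across-state mean with the average sd.
_MEDIATOR_STATS_NHE = {
    "IL-1b": ((9.6, 2.2), (7.2, 2.2), (6.8, 2.2)),
    "TNFa": ((8.5, 2.2), (5.3, 2.4), (4.9, 2.2)),
    "IL-1a": ((8.1, 2.0), (6.4, 2.2), (6.2, 1.9)),
    "IL-17A": ((1.8, 1.1), (2.4, 1.6), (1.7, 1.2)),
    "SAA": ((7.6, 2.2), (10.6, 2.2), (8.7, 1.7)),
    "IL-5": ((1.9, 1.3), (2.0, 1.3), (3.7, 2.2)),
    "Eotaxin-3": ((5.0, 2.0), (5.6, 1.9), (8.7, 2.8)),
    "TARC": ((3.3, 2.3), (4.5, 1.7), (6.8, 2.0)),
    "IL-8": ((15.7, 1.1), (14.6, 1.4), (13.8, 1.1)),
    "IL-16": ((5.5, 1.9), (7.4, 2.0), (8.4, 1.9)),
}


def _mediator_stats() -> dict[str, dict[str, tuple[float, float]]]:
    out: dict[str, dict[str, tuple[float, float]]] = {s: {} for s in STATES}
    for med, (nh, nb, e) in _MEDIATOR_STATS_NHE.items():
        out["NH"][med], out["NB"][med], out["E"][med] = nh, nb, e
        mid_mean = (nh[0] + nb[0] + e[0]) / 3
        mid_sd = (nh[1] + nb[1] + e[1]) / 3
        out["MIXED"][med] = (mid_mean, mid_sd)
        out["PAUCI"][med] = (mid_mean, mid_sd)
    return out


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, pre-filled with the defaults above."""

    n_patients: int = 100
    max_visits: int = 13
    visit_geometric_p: float = 0.30  # visits-per-patient ~ truncated geometric
    exacerbation_prob: float = 0.33  # visits after the first
    visit_gap_days: tuple[int, int] = (28, 90)
    sequencing_depth: int = 29_117
    states: tuple[str, ...] = STATES
    genera: tuple[str, ...] = GENERA
    initial_state_probs: np.ndarray = field(default_factory=lambda: _INITIAL.copy())
    stable_stable: np.ndarray = field(default_factory=lambda: _STABLE_STABLE.copy())
    stable_exac: np.ndarray = field(default_factory=lambda: _STABLE_EXAC.copy())
    community_mix: dict = field(default_factory=lambda: {k: dict(v) for k, v in _COMMUNITY_MIX.items()})
    concentrations: dict = field(default_factory=_default_concentrations)
    cell_stats: dict = field(default_factory=lambda: {s: dict(v) for s, v in _CELL_STATS.items()})
    mediator_stats: dict = field(default_factory=_mediator_stats)
    with_mediators: bool = True
    # eosinophilia coupling: genus -> multiplier strength on exp(z) scale
    eos_coupling: dict = field(
        default_factory=lambda: {
            "Campylobacter": 0.8,
            "Granulicatella": 0.8,
            "Capnocytophaga": 0.6,
            "Fusobacterium": 0.6,
            "Gemellaceae": 0.6,
        }
    )
    eos_pop_mean: float = 3.0  # standardisation of eosinophil % for coupling
    eos_pop_sd: float = 5.0
    eos_z_clip: float = 2.0  # saturation of the latent coupling factor
    # per-sample lognormal jitter on the dominant genus concentration of
    # dominated communities: varies the degree of overgrowth between samples
    dominance_jitter_sd: float = 0.4
    # genuine co-exclusion: genera suppressed (with genus-specific strength)
    # when the dominant genus overgrows. Differential strengths matter — a
    # uniform suppression would be indistinguishable from closure and
    # correctly ignored by compositional correlation estimators.
    dominance_coexclusion: dict = field(
        default_factory=lambda: {
            "Prevotella": 0.40,
            "Veillonella": 0.40,
            "Fusobacterium": 0.30,
            "Porphyromonas": 0.30,
            "Leptotrichia": 0.25,
            "Neisseria": 0.25,
            "Rothia": 0.20,
            "Actinomyces": 0.15,
            "Oribacterium": 0.15,
            "Lactobacillus": 0.15,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name, M in (("stable_stable", self.stable_stable), ("stable_exac", self.stable_exac)):
            M = np.asarray(M)
            if M.shape != (len(self.states),) * 2:
                raise ValueError(f"{name} matrix has wrong shape {M.shape}")
            if not np.allclose(M.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
            if (M < 0).any():
                raise ValueError(f"{name} has negative entries")
        if not np.isclose(np.sum(self.initial_state_probs), 1.0, atol=1e-9):
            raise ValueError("initial state probabilities must sum to 1")
        for kind, alpha in self.concentrations.items():
            if np.asarray(alpha).shape != (len(self.genera),):
                raise ValueError(f"concentration vector for {kind} has wrong length")
            if (np.asarray(alpha) <= 0).any():
                raise ValueError(f"Dirichlet concentrations for {kind} must be > 0")
        for state, mix in self.community_mix.items():
            if not np.isclose(sum(mix.values()), 1.0, atol=1e-9):
                raise ValueError(f"community mixture for {state} must sum to 1")

    def with_overrides(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)

    def persistence(self, state: str, context: str = "stable") -> float:
        i = self.states.index(state)
        M = self.stable_stable if context == "stable" else self.stable_exac
        return float(M[i, i])


def default_config(**kwargs) -> GeneratorConfig:
    cfg = GeneratorConfig(**kwargs)
    cfg.validate()
    return cfg


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated cohort."""

    sample_states: pd.Series  # sample_id -> NH/NB/E/MIXED/PAUCI
    sample_communities: pd.Series  # sample_id -> community kind
    patient_sequences: dict[str, list[str]]
    config: GeneratorConfig
    seed: int


# ---------------------------------------------------------------------------
# sampling primitives


def sample_state_sequence(
    config: GeneratorConfig,
    visit_types: list[str],
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Markov state sequence over the visit plan, conditioned on visit type.

    The transition into a visit uses the stable->exacerbation matrix when the
    destination visit is an exacerbation and the stable->stable matrix
    otherwise (transitions out of an exacerbation model recovery with the
    stable->stable matrix).
    """
    if not visit_types:
        raise ValueError("empty visit plan")
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = list(config.states)
    seq = [states[rng.choice(len(states), p=config.initial_state_probs)]]
    for vt in visit_types[1:]:
        M = config.stable_exac if vt == "exacerbation" else config.stable_stable
        row = M[states.index(seq[-1])]
        seq.append(states[rng.choice(len(states), p=row)])
    return seq


def sample_composition(
    state: str,
    config: GeneratorConfig,
    seed: int | np.random.Generator = 0,
    eos_z: float = 0.0,
    community: str | None = None,
    dominance_z: float | None = None,
) -> tuple[np.ndarray, str]:
    """Draw a genus composition for a state.

    Picks a community kind from the state's mixture (unless given), scales
    the eosinophil-coupled genera concentrations by exp(coupling * eos_z),
    applies the dominance jitter / co-exclusion factor (``dominance_z`` is
    the standard-normal colonisation propensity — a patient-level trait in
    cohort generation, drawn fresh when not supplied), and draws from the
    Dirichlet. Returns (composition, community kind).
    """
    if state not in config.states:
        raise ValueError(f"unknown state {state!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if community is None:
        mix = config.community_mix[state]
        kinds, probs = zip(*mix.items())
        community = kinds[rng.choice(len(kinds), p=np.asarray(probs))]
    alpha = np.asarray(config.concentrations[community], dtype=float).copy()
    if community != "balanced" and config.dominance_jitter_sd > 0:
        z = float(rng.normal()) if dominance_z is None else float(dominance_z)
        alpha[int(np.argmax(alpha))] *= float(np.exp(config.dominance_jitter_sd * z))
        for genus, strength in config.dominance_coexclusion.items():
            gi = config.genera.index(genus)
            # mean-preserving lognormal factor (E[exp(-sz - s^2/2)] = 1)
            alpha[gi] *= float(np.exp(-strength * z - strength**2 / 2.0))
    if eos_z != 0.0:
        z = float(np.clip(eos_z, -config.eos_z_clip, config.eos_z_clip))
        for genus, coupling in config.eos_coupling.items():
            gi = config.genera.index(genus)
            alpha[gi] *= float(np.exp(coupling * z))
    comp = rng.dirichlet(alpha)
    return comp, community


@lru_cache(maxsize=None)
def matched_truncnorm_loc(target_mean: float, sd: float, low: float = 0.0, high: float = 100.0) -> float:
    """Location parameter whose [low, high]-truncated normal has the target mean.

    The configured cell-count moments are realised subgroup means, so the
    underlying location is solved for rather than set to the target (a
    normal truncated at 100 % with loc 88.8 would realise a mean near 86).
    """
    from scipy.optimize import brentq
    from scipy.stats import truncnorm

    def realised(loc: float) -> float:
        a, b = (low - loc) / sd, (high - loc) / sd
        return float(truncnorm.mean(a, b, loc=loc, scale=sd))

    lo, hi = target_mean - 6 * sd, target_mean + 6 * sd
    return float(brentq(lambda L: realised(L) - target_mean, lo, hi, xtol=1e-8))


@lru_cache(maxsize=None)
def truncated_cell_distribution(target_mean: float, sd: float):
    """Frozen scipy truncnorm realising the target mean on [0, 100]."""
    from scipy.stats import truncnorm

    loc = matched_truncnorm_loc(target_mean, sd)
    a, b = (0.0 - loc) / sd, (100.0 - loc) / sd
    return truncnorm(a, b, loc=loc, scale=sd)


def _draw_cells(rng: np.random.Generator, config: GeneratorConfig, state: str) -> dict[str, float]:
    """Truncated-normal cell percentages, jointly constrained to <= 100.

    The granulocyte classes (neutrophils, eosinophils) keep their draws —
    their subgroup means are the calibrated quantities — and the remaining
    classes are rescaled proportionally into whatever room is left.
    """
    cells = {
        col: float(truncated_cell_distribution(m, s).ppf(rng.uniform()))
        for col, (m, s) in config.cell_stats[state].items()
    }
    granulo = cells.get("neutrophil_pct", 0.0) + cells.get("eosinophil_pct", 0.0)
    if granulo > 100.0:  # essentially never under the default moments
        cells["neutrophil_pct"] *= 100.0 / granulo
        cells["eosinophil_pct"] *= 100.0 / granulo
        granulo = 100.0
    others = [k for k in cells if k not in ("neutrophil_pct", "eosinophil_pct")]
    other_sum = sum(cells[k] for k in others)
    if other_sum > 100.0 - granulo:
        scale = (100.0 - granulo) / other_sum if other_sum > 0 else 0.0
        for k in others:
            cells[k] *= scale
    return cells


_SEASONS = ("winter", "spring", "summer", "autumn")


def _season_of(day_of_year: int) -> str:
    # meteorological quarters: DJF / MAM / JJA / SON
    month = (day_of_year % 365) // 30 + 1
    return _SEASONS[{12: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1, 6: 2, 7: 2, 8: 2, 9: 3, 10: 3, 11: 3}[min(month, 12)]]


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> tuple[CohortDataset, SyntheticTruth]:
    """Generate a full longitudinal cohort plus its ground truth.

    Fully reproducible: the same config and seed give byte-identical output.
    """
    config = config or default_config()
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    abundance_rows, meta_rows = [], []
    truth_states, truth_comms = {}, {}
    sequences: dict[str, list[str]] = {}

    for p in range(config.n_patients):
        pid = f"P{p:04d}"
        n_visits = int(min(rng.geometric(config.visit_geometric_p), config.max_visits))
        visit_types = ["stable"] + [
            "exacerbation" if rng.uniform() < config.exacerbation_prob else "stable"
            for _ in range(n_visits - 1)
        ]
        states = sample_state_sequence(config, visit_types, rng)
        sequences[pid] = states

        base_doy = int(rng.integers(0, 365))
        dominance_z = float(rng.normal())  # colonisation propensity, stable per patient
        age = float(np.round(rng.normal(68.0, 8.0), 1))
        sex = "F" if rng.uniform() < 0.30 else "M"
        bmi = float(np.round(rng.normal(27.0, 5.0), 1))
        smoking = bool(rng.uniform() < 0.60)
        ics = bool(rng.uniform() < 0.85)

        day = 0
        for v, (vt, state) in enumerate(zip(visit_types, states), start=1):
            sid = f"{pid}V{v:02d}"
            if v > 1:
                day += int(rng.integers(config.visit_gap_days[0], config.visit_gap_days[1] + 1))
            cells = _draw_cells(rng, config, state)
            eos_z = (cells["eosinophil_pct"] - config.eos_pop_mean) / config.eos_pop_sd
            comp, community = sample_composition(
                state, config, rng, eos_z=eos_z, dominance_z=dominance_z
            )
            counts = rng.multinomial(config.sequencing_depth, comp)
            abundance_rows.append((sid, counts))
            row = {
                "sample_id": sid,
                "patient_id": pid,
                "site": "synthetic",
                "visit_index": v,
                "day_offset": day,
                "visit_type": vt,
                "season": _season_of(base_doy + day),
                "age": age,
                "sex": sex,
                "bmi": bmi,
                "smoking": smoking,
                "ics": ics,
                **cells,
            }
            if config.with_mediators:
                for med, (m, s) in config.mediator_stats[state].items():
                    row[f"mediator_{med}"] = float(rng.normal(m, s))
            meta_rows.append(row)
            truth_states[sid] = state
            truth_comms[sid] = community

    sample_ids = [sid for sid, _ in abundance_rows]
    table = GenusAbundanceTable(
        pd.DataFrame(
            np.vstack([c for _, c in abundance_rows]),
            index=sample_ids,
            columns=list(config.genera),
        ),
        kind="counts",
    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    dataset = CohortDataset(table=table, metadata=SampleMetadata(meta))
    truth = SyntheticTruth(
        sample_states=pd.Series(truth_states, name="state").loc[sample_ids],
        sample_communities=pd.Series(truth_comms, name="community").loc[sample_ids],
        patient_sequences=sequences,
        config=config,
        seed=seed,
    )
    assert set(truth.sample_states.index) == set(sample_ids)
    return dataset, truth
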