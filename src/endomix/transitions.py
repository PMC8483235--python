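"""Within-patient inflammatory-state transitions and covariate odds ratios.

The joint endotype x community-type label collapses to the three analysed
states: NH (neutrophilic, Haemophilus-predominant), NB (neutrophilic,
balanced community) and E (eosinophilic, any community). Everything else —
mixed or paucigranulocytic endotypes, unassigned samples, neutrophilic
samples in Moraxella/Streptococcus-predominant communities — is EXCLUDED
from the transition analysis, and consecutive-pair tables are built from
the chronologically adjacent remaining visits of each patient, separately
for the stable–stable and stable–exacerbation contexts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core_io import CohortDataset

__all__ = [
    "TRANSITION_STATES",
    "TransitionTable",
    "OddsRatioResult",
    "derive_states",
    "transition_table",
    "covariate_switch_or",
    "odds_ratio_from_counts",
    "transition_pairs",
]

TRANSITION_STATES = ("NH", "NB", "E")
CONTEXTS = ("stable-stable", "stable-exacerbation")


def derive_states(endotypes: pd.Series, community_names: pd.Series) -> pd.Series:
    """Collapse endotype x community type to NH / NB / E / EXCLUDED."""
    out = {}
    for sid in endotypes.index:
        endo = endotypes[sid]
        comm = community_names.get(sid, "")
        comm = "" if pd.isna(comm) else str(comm)
        if endo == "neutrophilic" and comm.startswith("Haemophilus"):
            out[sid] = "NH"
        elif endo == "neutrophilic" and comm.startswith("balanced"):
            out[sid] = "NB"
        elif endo == "eosinophilic":
            out[sid] = "E"
        else:
            out[sid] = "EXCLUDED"
    return pd.Series(out, name="state").loc[endotypes.index]


@dataclass
class TransitionTable:
    context: str
    counts: pd.DataFrame  # from-state x to-state

    @property
    def n_pairs(self) -> int:
        return int(self.counts.to_numpy().sum())

    def persistence(self, state: str) -> float:
        row = self.counts.loc[state]
        total = row.sum()
        if total == 0:
            return np.nan
        return float(self.counts.loc[state, state] / total)

    def persistences(self) -> dict[str, float]:
        return {s: self.persistence(s) for s in self.counts.index}


def transition_pairs(dataset: CohortDataset, states: pd.Series) -> pd.DataFrame:
    """Consecutive same-patient visit pairs with analysable states.

    Pairs are formed from chronologically consecutive visits; a pair is
    dropped when either member's state is EXCLUDED (mixed/paucigranulocytic
    or unassignable samples break the chain rather than bridging it).
    Contexts: both visits stable -> stable-stable; stable followed by
    exacerbation -> stable-exacerbation; pairs starting at an exacerbation
    are not analysed and receive context ``None``.
    """
    meta = dataset.aligned_metadata()
    rows = []
    for pid, grp in meta.groupby("patient_id"):
        ordered = grp.sort_values("day_offset")
        sids = ordered.index.tolist()
        for a, b in zip(sids[:-1], sids[1:]):
            if states.get(a, "EXCLUDED") == "EXCLUDED" or states.get(b, "EXCLUDED") == "EXCLUDED":
                continue
            vt_a, vt_b = meta.loc[a, "visit_type"], meta.loc[b, "visit_type"]
            if vt_a == "stable" and vt_b == "stable":
                context = "stable-stable"
            elif vt_a == "stable" and vt_b == "exacerbation":
                context = "stable-exacerbation"
            else:
                context = None
            rows.append(
                {
                    "patient_id": pid,
                    "from_sample": a,
                    "to_sample": b,
                    "from_state": states[a],
                    "to_state": states[b],
                    "context": context,
                    "from_season": meta.loc[a].get("season"),
                    "to_season": meta.loc[b].get("season"),
                    "ics": meta.loc[a].get("ics"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "from_sample", "to_sample", "from_state", "to_state",
            "context", "from_season", "to_season", "ics",
        ],
    )


def transition_table(dataset: CohortDataset, states: pd.Series) -> dict[str, TransitionTable]:
    """Per-context from-state x to-state transition counts and persistences."""
    meta = dataset.aligned_metadata()
    for pid, grp in meta.groupby("patient_id"):
        ordered = grp.sort_values("visit_index")
        if not ordered["day_offset"].is_monotonic_increasing:
            raise ValueError(f"patient {pid}: visits are not chronologically ordered")
    pairs = transition_pairs(dataset, states)
    out = {}
    for context in CONTEXTS:
        counts = pd.DataFrame(0, index=list(TRANSITION_STATES), columns=list(TRANSITION_STATES))
        if not pairs.empty:
            sub = pairs[pairs["context"] == context]
            for _, row in sub.iterrows():
                counts.loc[row["from_state"], row["to_state"]] += 1
        out[context] = TransitionTable(context=context, counts=counts)
    return out


# ---------------------------------------------------------------------------
# odds ratios


@dataclass
class OddsRatioResult:
    a: float
    b: float
    c: float
    d: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    continuity_corrected: bool

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValueError("CI must bracket the odds ratio")


def odds_ratio_from_counts(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """OR = ad/bc with Haldane–Anscombe +0.5 on any zero cell and Woolf CI.

    The two-sided p comes from the log-OR z statistic.
    """
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 if corrected else x for x in (a, b, c, d))
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = np.log(or_)
    z = log_or / se
    p = float(2 * norm.sf(abs(z)))
    ci_low = float(np.exp(log_or - 1.959963984540054 * se))
    ci_high = float(np.exp(log_or + 1.959963984540054 * se))
    return OddsRatioResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=float(or_), ci_low=ci_low, ci_high=ci_high,
        p_value=p, continuity_corrected=corrected,
    )


def covariate_switch_or(
    switch_indicator: np.ndarray, covariate_indicator: np.ndarray
) -> OddsRatioResult:
    """Association between a binary covariate and state switches over pairs.

    The 2x2 table is (covariate x switch); cells:
    a = covariate & switch, b = covariate & no switch,
    c = no covariate & switch, d = no covariate & no switch.
    """
    s = np.asarray(switch_indicator).astype(bool)
    x = np.asarray(covariate_indicator).astype(bool)
    if s.shape != x.shape:
        raise ValueError("indicators must have equal length")
    if s.all() or (~s).all():
        raise ValueError("switch indicator is constant")
    if x.all() or (~x).all():
        raise ValueError("covariate indicator is constant")
    a = int((x & s).sum())
    b = int((x & ~s).sum())
    c = int((~x & s).sum())
    d = int((~x & ~s).sum())
    return odds_ratio_from_counts(a, b, c, d)


def seasonal_change_indicator(pairs: pd.DataFrame) -> np.ndarray:
    """True where the two visits of a pair fall in different meteorological quarters."""
    return (pairs["from_season"] != pairs["to_season"]).to_numpy()


def endotype_switch_indicator(pairs: pd.DataFrame) -> np.ndarray:
    """True where a pair switches between neutrophilic (NH/NB) and E."""
    frm = pairs["from_state"].isin(("NH", "NB"))
    to = pairs["to_state"].isin(("NH", "NB"))
    return (frm != to).to_numpy()
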