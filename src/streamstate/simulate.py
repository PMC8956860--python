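"""Synthetic occurrence data with known ground truth.

The generator draws genus-level permanence (psi) and recolonization (theta)
probabilities around group means from a Beta hierarchy, then simulates each
substrate series as a two-state occupancy chain: an unoccupied unit is
colonized with probability theta, an occupied one persists with probability
psi (times the treatment deviation delta of its intensity x frequency cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignSpec, build_design
from .panel import HYPOTHESIS_BANDS, TREATMENT_CELLS, OccurrencePanel, load_trait_table

__all__ = ["GroupTruth", "TrueParams", "simulate_panel", "simulate_before_after"]

_PROB_FLOOR = 1e-6

#: Representative probability for each hypothesis band (band midpoint,
#: with "very high" at the centre of its narrower band).
_BAND_VALUE = {"low": 0.17, "moderate": 0.5, "high": 0.83, "very high": 0.9}


def _clamp(p):
    return np.clip(p, _PROB_FLOOR, 1.0 - _PROB_FLOOR)


@dataclass(frozen=True)
class GroupTruth:
    """True group-level parameters for one life-history strategy group."""

    theta: float
    psi: float
    n_genera: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.theta < 1 and 0 < self.psi < 1):
            raise ValueError("theta and psi must be in (0, 1)")
        if self.n_genera < 1:
            raise ValueError("each group needs at least one genus")


@dataclass(frozen=True)
class TrueParams:
    """Ground truth for a synthetic experiment.

    Parameters
    ----------
    groups
        Group id -> :class:`GroupTruth`.
    kappa
        Beta concentration for genus-level draws around the group mean;
        ``theta_i ~ Beta(kappa * theta_g, kappa * (1 - theta_g))`` and
        likewise for psi.  ``np.inf`` pins every genus at its group mean.
    delta
        Treatment cell -> {group id -> permanence deviation}; 1 means no
        deviation (the control value).  Missing cells/groups default to 1.
    effect
        Group id -> immediate-effect multiplier e_g on the occurrence
        probability right after a single disturbance.
    before_prob
        Group id -> occurrence probability b_g just before that disturbance.
    """

    groups: dict[int, GroupTruth]
    kappa: float = 50.0
    delta: dict[str, dict[int, float]] = field(default_factory=dict)
    effect: dict[int, float] = field(default_factory=dict)
    before_prob: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        unknown = set(self.delta) - set(TREATMENT_CELLS)
        if unknown:
            raise ValueError(f"unknown treatment cells: {sorted(unknown)}")

    @classmethod
    def from_hypotheses(cls, n_genera_per_group: int = 4, **kwargs) -> "TrueParams":
        """Truth with each group's (psi, theta) at its hypothesized level.

        Uses the packaged nine-group trait table and representative values
        per ordinal band, giving a community whose strategy structure mirrors
        the hypothesized one.
        """
        table = load_trait_table()
        groups: dict[int, GroupTruth] = {}
        for g in sorted({rec.group for rec in table}):
            rec = next(r for r in table if r.group == g)
            groups[g] = GroupTruth(
                theta=_BAND_VALUE[rec.theta_hypothesis],
                psi=_BAND_VALUE[rec.psi_hypothesis],
                n_genera=n_genera_per_group,
                name=f"group{g}",
            )
        return cls(groups=groups, **kwargs)

    def delta_for(self, cell: str, group: int) -> float:
        if cell == "C":
            return 1.0
        return float(self.delta.get(cell, {}).get(group, 1.0))

    def genus_names(self) -> list[str]:
        names = []
        for g in sorted(self.groups):
            spec = self.groups[g]
            base = spec.name or f"group{g}"
            names.extend(f"{base}_genus{j + 1}" for j in range(spec.n_genera))
        return names

    def genus_groups(self) -> dict[str, int]:
        out = {}
        for g in sorted(self.groups):
            spec = self.groups[g]
            base = spec.name or f"group{g}"
            for j in range(spec.n_genera):
                out[f"{base}_genus{j + 1}"] = g
        return out


def _draw_genus_probs(rng: np.random.Generator, mean: float, kappa: float, n: int) -> np.ndarray:
    if np.isinf(kappa):
        return np.full(n, mean)
    return _clamp(rng.beta(kappa * mean, kappa * (1.0 - mean), size=n))


def simulate_panel(
    true_params: TrueParams,
    spec: DesignSpec | None = None,
    rng_seed: int | None = None,
    init: str = "stationary",
) -> tuple[OccurrencePanel, pd.DataFrame]:
    """Simulate a full factorial occurrence panel.

    Each series follows ``O_t ~ Bernoulli(clamp(theta_i + O_{t-1} * psi_i *
    delta))`` for occasions t >= 2.  The first occasion is drawn from the
    quasi-stationary occupancy ``theta_i / (1 - psi_i * delta)`` by default
    (substrates had been colonizing for weeks before the first collection);
    ``init="empty"`` instead starts empty and burns in 23 daily steps.

    Returns the panel and a table of the genus-level true parameters.
    """
    if init not in ("stationary", "empty"):
        raise ValueError("init must be 'stationary' or 'empty'")
    spec = spec or DesignSpec()
    rng = np.random.default_rng(rng_seed)

    genera = true_params.genus_names()
    genus_group = true_params.genus_groups()
    group_of = np.array([genus_group[g] for g in genera])

    theta_i = np.empty(len(genera))
    psi_i = np.empty(len(genera))
    for g in sorted(true_params.groups):
        mask = group_of == g
        spec_g = true_params.groups[g]
        theta_i[mask] = _draw_genus_probs(rng, spec_g.theta, true_params.kappa, mask.sum())
        psi_i[mask] = _draw_genus_probs(rng, spec_g.psi, true_params.kappa, mask.sum())

    units = build_design(spec)
    series_meta = (
        units[["stream", "frequency", "battery", "cell"]]
        .drop_duplicates()
        .sort_values(["stream", "frequency", "battery"])
        .reset_index(drop=True)
    )
    n_g, n_s, n_t = len(genera), len(series_meta), spec.n_columns

    delta_s = np.empty((n_g, n_s))
    for si, cell in enumerate(series_meta["cell"]):
        for gi, g in enumerate(group_of):
            delta_s[gi, si] = true_params.delta_for(cell, int(g))

    th = theta_i[:, None]
    ps = psi_i[:, None]
    occ = np.empty((n_g, n_s, n_t), dtype=np.int8)
    if init == "stationary":
        p0 = _clamp(th / (1.0 - np.clip(ps * delta_s, None, 1.0 - _PROB_FLOOR)))
        state = (rng.random((n_g, n_s)) < p0).astype(np.int8)
    else:
        state = np.zeros((n_g, n_s), dtype=np.int8)
        for _ in range(spec.start_day):
            p = _clamp(th + state * ps * delta_s)
            state = (rng.random((n_g, n_s)) < p).astype(np.int8)
    occ[:, :, 0] = state
    for t in range(1, n_t):
        p = _clamp(th + state * ps * delta_s)
        state = (rng.random((n_g, n_s)) < p).astype(np.int8)
        occ[:, :, t] = state

    panel = OccurrencePanel(
        occurrences=occ,
        genera=genera,
        series_meta=series_meta[["stream", "frequency", "battery"]].copy(),
        occasion_days=np.asarray(spec.occasion_days()),
        genus_group=genus_group,
    )
    truth = pd.DataFrame(
        {"genus": genera, "group": group_of, "theta": theta_i, "psi": psi_i}
    )
    return panel, truth


def simulate_before_after(
    b_g: float,
    e_g: float,
    n: int,
    n_genera: int,
    rng_seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Before/after occurrence counts for the immediate-effect experiment.

    ``B_i ~ Binomial(n, b_g)`` and ``A_i ~ Binomial(n, clamp(b_g * e_g))``
    where n is the number of paired substrate units (one per stream under
    the field design) and e_g the multiplicative effect of the disturbance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= b_g <= 1:
        raise ValueError("b_g must be a probability")
    if e_g < 0:
        raise ValueError("e_g must be non-negative")
    rng = np.random.default_rng(rng_seed)
    a = float(np.clip(b_g * e_g, 0.0, 1.0 - _PROB_FLOOR))
    before = rng.binomial(n, b_g, size=n_genera)
    after = rng.binomial(n, a, size=n_genera)
    return before, after
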