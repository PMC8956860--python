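"""The three fitted models: baseline, immediate effect, and treatment.

All three are Metropolis-within-Gibbs fits of hierarchical Bayesian models:

* :class:`BaselineOccupancy` — genus-level recolonization (theta) and
  permanence (psi) probabilities on control series, tied to their functional
  group through Beta(alpha, beta) priors whose hyperparameters get vague
  Gamma(0.001, 0.001) priors.
* :class:`ImmediateEffect` — before/after binomial occurrence counts around
  a single disturbance, with a group-level multiplicative effect e_g.
* :class:`TreatmentOccupancy` — the baseline model extended with a
  permanence deviation delta_{k,g} per intensity x frequency treatment cell,
  with a diffuse Normal(0, sd 31.62) prior; the control cell is fixed at
  delta = 1.

The estimators follow the scikit-learn protocol (``fit`` plus fitted
attributes with trailing underscores); module-level ``fit_*`` functions are
thin wrappers.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import special
from sklearn.base import BaseEstimator

from .mcmc import MCMCConfig, PosteriorDraws, PROB_FLOOR
from .panel import (
    HYPOTHESIS_BANDS,
    TREATMENT_CELLS,
    CredibleSummary,
    OccurrencePanel,
    TraitRecord,
)

__all__ = [
    "BaselineOccupancy",
    "ImmediateEffect",
    "TreatmentOccupancy",
    "fit_baseline",
    "fit_immediate",
    "fit_treatment",
    "hypothesis_check",
]

_HYPER_LO, _HYPER_HI = 1e-3, 1e3
_GAMMA_SHAPE = _GAMMA_RATE = 0.001
_DELTA_SD = 1.0 / np.sqrt(0.001)  # precision-0.001 Normal, effectively flat


def _clamp(p):
    return np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(z):
    return special.expit(z)


def _log_beta_pdf(x, a, b):
    return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - special.betaln(a, b)


def _log_gamma_pdf(x, shape, rate):
    return (shape - 1.0) * np.log(x) - rate * x


# ---------------------------------------------------------------------------
# Sufficient statistics

class _PanelStats:
    """Per-genus transition counts by treatment cell.

    With a constant permanence deviation per cell, the series likelihood
    depends on the data only through, per genus and cell, the number of
    empty->any transitions (n0), colonizations among them (k0), occupied->any
    transitions (n1) and persistences among them (k1).
    """

    def __init__(self, panel: OccurrencePanel, cells: Sequence[str]):
        self.cells = list(cells)
        self.genera = list(panel.genera)
        self.group_of = np.array([panel.genus_group[g] for g in panel.genera])
        self.groups = sorted(set(self.group_of))
        labels = panel.series_cells()
        n_g, n_c = panel.n_genera, len(self.cells)
        self.n0 = np.zeros((n_g, n_c))
        self.k0 = np.zeros((n_g, n_c))
        self.n1 = np.zeros((n_g, n_c))
        self.k1 = np.zeros((n_g, n_c))
        for ci, cell in enumerate(self.cells):
            mask = labels == cell
            if not mask.any():
                continue
            prev = panel.occurrences[:, mask, :-1]
            cur = panel.occurrences[:, mask, 1:]
            empty = prev == 0
            self.n0[:, ci] = empty.sum(axis=(1, 2))
            self.k0[:, ci] = (empty & (cur == 1)).sum(axis=(1, 2))
            self.n1[:, ci] = (~empty).sum(axis=(1, 2))
            self.k1[:, ci] = (~empty & (cur == 1)).sum(axis=(1, 2))

    def loglik(self, theta: np.ndarray, psi: np.ndarray, delta_gc: np.ndarray, link: str) -> np.ndarray:
        """Per-genus log-likelihood given genus params and per-cell deviations."""
        p0 = _clamp(theta)[:, None]
        if link == "literal":
            p1 = _clamp(theta[:, None] + psi[:, None] * delta_gc)
        else:
            p1 = _clamp(psi[:, None] * delta_gc)
        ll = self.k0 * np.log(p0) + (self.n0 - self.k0) * np.log1p(-p0)
        ll += self.k1 * np.log(p1) + (self.n1 - self.k1) * np.log1p(-p1)
        return ll.sum(axis=1)

    def loglik_cell(self, theta, psi, delta_c, ci: int, rows: np.ndarray, link: str) -> float:
        """Occupied-transition log-likelihood of one cell for a genus subset."""
        th, ps = theta[rows], psi[rows]
        if link == "literal":
            p1 = _clamp(th + ps * delta_c)
        else:
            p1 = _clamp(ps * delta_c)
        return float(
            (self.k1[rows, ci] * np.log(p1) + (self.n1[rows, ci] - self.k1[rows, ci]) * np.log1p(-p1)).sum()
        )


# ---------------------------------------------------------------------------
# The blocked sampler shared by baseline and treatment fits


class _AdaptiveScale:
    """Proposal scale tuned toward 20-50% acceptance during burn-in only."""

    def __init__(self, value: float):
        self.value = value
        self.accepted = 0.0
        self.proposed = 0

    def record(self, acc, n=1):
        self.accepted += float(acc)
        self.proposed += n

    def maybe_adapt(self):
        if self.proposed >= 50:
            rate = self.accepted / self.proposed
            if rate < 0.20:
                self.value *= 0.7
            elif rate > 0.50:
                self.value *= 1.4
            self.accepted = 0.0
            self.proposed = 0


def _run_occupancy_sampler(
    stats: _PanelStats,
    config: MCMCConfig,
    freeze_hyperparams: tuple[float, float, float, float] | None,
    sample_delta: bool,
    fixed_genus_params: tuple[np.ndarray, np.ndarray] | None = None,
) -> PosteriorDraws:
    n_g = len(stats.genera)
    groups = stats.groups
    cells = stats.cells
    trt_cells = [c for c in cells if c != "C"]
    link = config.link
    group_rows = {g: np.where(stats.group_of == g)[0] for g in groups}

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains)

    n_keep = config.draws_per_chain
    kept: dict[str, np.ndarray] = {}

    def keep_slot(name):
        kept[name] = np.empty((config.n_chains, n_keep))

    sample_genus = fixed_genus_params is None
    if sample_genus:
        for g_name in stats.genera:
            keep_slot(f"theta[{g_name}]")
            keep_slot(f"psi[{g_name}]")
    if freeze_hyperparams is None and sample_genus:
        for g in groups:
            for h in ("alpha1", "beta1", "alpha2", "beta2"):
                keep_slot(f"{h}[{g}]")
            keep_slot(f"theta_group[{g}]")
            keep_slot(f"psi_group[{g}]")
    if sample_delta:
        for cell in trt_cells:
            for g in groups:
                keep_slot(f"delta[{cell},{g}]")

    acc_tot = {"theta": [0.0, 0], "psi": [0.0, 0], "hyper": [0.0, 0], "delta": [0.0, 0]}

    for c_idx, seed in enumerate(chain_seeds):
        rng = np.random.default_rng(seed)

        # moment-based initialization, jittered per chain
        if sample_genus:
            theta = _clamp((stats.k0.sum(axis=1) + 1.0) / (stats.n0.sum(axis=1) + 2.0))
            raw_p1 = _clamp((stats.k1.sum(axis=1) + 1.0) / (stats.n1.sum(axis=1) + 2.0))
            psi = _clamp(raw_p1 - theta) if link == "literal" else raw_p1
            theta = _expit(_logit(theta) + 0.3 * rng.standard_normal(n_g))
            psi = _expit(_logit(psi) + 0.3 * rng.standard_normal(n_g))
        else:
            theta, psi = (np.asarray(a, dtype=float).copy() for a in fixed_genus_params)
        hyper = {}
        for g in groups:
            if freeze_hyperparams is not None:
                hyper[g] = np.asarray(freeze_hyperparams, dtype=float)
            else:
                rows = group_rows[g]
                m1, m2 = theta[rows].mean(), psi[rows].mean()
                hyper[g] = np.array([10 * m1, 10 * (1 - m1), 10 * m2, 10 * (1 - m2)])
        delta = {(cell, g): 1.0 for cell in trt_cells for g in groups}

        delta_gc = np.ones((n_g, len(cells)))

        def refresh_delta_gc():
            for ci, cell in enumerate(cells):
                if cell == "C":
                    continue
                for g in groups:
                    delta_gc[group_rows[g], ci] = delta[(cell, g)]

        refresh_delta_gc()

        def genus_prior(th, ps):
            a1 = np.array([hyper[g][0] for g in stats.group_of])
            b1 = np.array([hyper[g][1] for g in stats.group_of])
            a2 = np.array([hyper[g][2] for g in stats.group_of])
            b2 = np.array([hyper[g][3] for g in stats.group_of])
            return _log_beta_pdf(th, a1, b1) + _log_beta_pdf(ps, a2, b2)

        s_theta = _AdaptiveScale(config.step_logit)
        s_psi = _AdaptiveScale(config.step_logit)
        s_pair = _AdaptiveScale(config.step_logit)
        s_hyper = {g: _AdaptiveScale(config.step_log) for g in groups}
        s_delta = {key: _AdaptiveScale(config.step_identity) for key in delta}

        ll = stats.loglik(theta, psi, delta_gc, link)
        lprior = genus_prior(theta, psi)

        k = 0
        # logit-scale proposals can land on exactly 0/1 in floating point;
        # the resulting -inf/nan comparisons correctly reject, so silence them
        errstate = np.errstate(divide="ignore", invalid="ignore")
        errstate.__enter__()
        for it in range(config.total_steps):
            burn = it < config.burn_in
            if sample_genus:
                # --- genus-level theta (vectorized element-wise MH) -------------
                z = _logit(theta) + s_theta.value * rng.standard_normal(n_g)
                theta_new = _expit(z)
                ll_new = stats.loglik(theta_new, psi, delta_gc, link)
                lp_new = genus_prior(theta_new, psi)
                jac = np.log(theta_new) + np.log1p(-theta_new) - np.log(theta) - np.log1p(-theta)
                accept = np.log(rng.random(n_g)) < (ll_new - ll + lp_new - lprior + jac)
                theta = np.where(accept, theta_new, theta)
                ll = np.where(accept, ll_new, ll)
                lprior = np.where(accept, lp_new, lprior)
                s_theta.record(accept.mean())
                if not burn:
                    acc_tot["theta"][0] += accept.mean()
                    acc_tot["theta"][1] += 1

                # --- genus-level psi --------------------------------------------
                z = _logit(psi) + s_psi.value * rng.standard_normal(n_g)
                psi_new = _expit(z)
                ll_new = stats.loglik(theta, psi_new, delta_gc, link)
                lp_new = genus_prior(theta, psi_new)
                jac = np.log(psi_new) + np.log1p(-psi_new) - np.log(psi) - np.log1p(-psi)
                accept = np.log(rng.random(n_g)) < (ll_new - ll + lp_new - lprior + jac)
                psi = np.where(accept, psi_new, psi)
                ll = np.where(accept, ll_new, ll)
                lprior = np.where(accept, lp_new, lprior)
                s_psi.record(accept.mean())
                if not burn:
                    acc_tot["psi"][0] += accept.mean()
                    acc_tot["psi"][1] += 1

                # --- joint anti-correlated (theta, psi) move --------------------
                # under the literal link the occupied-state probability is
                # theta + psi * delta, so the pair is negatively correlated;
                # moving along that ridge speeds mixing considerably
                eps = s_pair.value * rng.standard_normal(n_g)
                theta_new = _expit(_logit(theta) + eps)
                psi_new = _expit(_logit(psi) - eps)
                ll_new = stats.loglik(theta_new, psi_new, delta_gc, link)
                lp_new = genus_prior(theta_new, psi_new)
                jac = (
                    np.log(theta_new) + np.log1p(-theta_new) - np.log(theta) - np.log1p(-theta)
                    + np.log(psi_new) + np.log1p(-psi_new) - np.log(psi) - np.log1p(-psi)
                )
                accept = np.log(rng.random(n_g)) < (ll_new - ll + lp_new - lprior + jac)
                theta = np.where(accept, theta_new, theta)
                psi = np.where(accept, psi_new, psi)
                ll = np.where(accept, ll_new, ll)
                lprior = np.where(accept, lp_new, lprior)
                s_pair.record(accept.mean())

            # --- hyperparameters, one group at a time -----------------------
            if freeze_hyperparams is None and sample_genus:
                for g in groups:
                    rows = group_rows[g]
                    h = hyper[g]
                    for pair, x in (((0, 1), theta), ((2, 3), psi)):
                        ia, ib = pair
                        # three move types: log-RW on a, on b, joint rescale
                        for move in range(3):
                            a, b = h[ia], h[ib]
                            eps = rng.standard_normal()
                            if move == 0:
                                a_new, b_new = a * np.exp(s_hyper[g].value * eps), b
                                ljac = np.log(a_new) - np.log(a)
                            elif move == 1:
                                a_new, b_new = a, b * np.exp(s_hyper[g].value * eps)
                                ljac = np.log(b_new) - np.log(b)
                            else:
                                f = np.exp(s_hyper[g].value * eps)
                                a_new, b_new = a * f, b * f
                                ljac = np.log(a_new * b_new) - np.log(a * b)
                            u = rng.random()
                            if not (_HYPER_LO <= a_new <= _HYPER_HI and _HYPER_LO <= b_new <= _HYPER_HI):
                                s_hyper[g].record(0)
                                continue
                            x_g = x[rows]
                            lp_old = (
                                _log_beta_pdf(x_g, a, b).sum()
                                + _log_gamma_pdf(a, _GAMMA_SHAPE, _GAMMA_RATE)
                                + _log_gamma_pdf(b, _GAMMA_SHAPE, _GAMMA_RATE)
                            )
                            lp_new = (
                                _log_beta_pdf(x_g, a_new, b_new).sum()
                                + _log_gamma_pdf(a_new, _GAMMA_SHAPE, _GAMMA_RATE)
                                + _log_gamma_pdf(b_new, _GAMMA_SHAPE, _GAMMA_RATE)
                            )
                            acc = np.log(u) < lp_new - lp_old + ljac
                            if acc:
                                h[ia], h[ib] = a_new, b_new
                            s_hyper[g].record(acc)
                            if not burn:
                                acc_tot["hyper"][0] += acc
                                acc_tot["hyper"][1] += 1
                    lprior = genus_prior(theta, psi)

            # --- treatment deviations ---------------------------------------
            if sample_delta:
                for ci, cell in enumerate(cells):
                    if cell == "C":
                        continue
                    for g in groups:
                        rows = group_rows[g]
                        key = (cell, g)
                        d = delta[key]
                        d_new = d + s_delta[key].value * rng.standard_normal()
                        u = rng.random()
                        lp_old = stats.loglik_cell(theta, psi, d, ci, rows, link) - d**2 / (2 * _DELTA_SD**2)
                        lp_new = stats.loglik_cell(theta, psi, d_new, ci, rows, link) - d_new**2 / (2 * _DELTA_SD**2)
                        acc = np.log(u) < lp_new - lp_old
                        if acc:
                            delta[key] = d_new
                            delta_gc[rows, ci] = d_new
                        s_delta[key].record(acc)
                        if not burn:
                            acc_tot["delta"][0] += acc
                            acc_tot["delta"][1] += 1
                if sample_delta and trt_cells:
                    ll = stats.loglik(theta, psi, delta_gc, link)

            if burn:
                s_theta.maybe_adapt()
                s_psi.maybe_adapt()
                s_pair.maybe_adapt()
                for sc in s_hyper.values():
                    sc.maybe_adapt()
                for sc in s_delta.values():
                    sc.maybe_adapt()
            elif (it - config.burn_in) % config.thin == 0 and k < n_keep:
                if sample_genus:
                    for gi, g_name in enumerate(stats.genera):
                        kept[f"theta[{g_name}]"][c_idx, k] = theta[gi]
                        kept[f"psi[{g_name}]"][c_idx, k] = psi[gi]
                    if freeze_hyperparams is None:
                        for g in groups:
                            a1, b1, a2, b2 = hyper[g]
                            kept[f"alpha1[{g}]"][c_idx, k] = a1
                            kept[f"beta1[{g}]"][c_idx, k] = b1
                            kept[f"alpha2[{g}]"][c_idx, k] = a2
                            kept[f"beta2[{g}]"][c_idx, k] = b2
                            kept[f"theta_group[{g}]"][c_idx, k] = a1 / (a1 + b1)
                            kept[f"psi_group[{g}]"][c_idx, k] = a2 / (a2 + b2)
                for key in delta if sample_delta else ():
                    kept[f"delta[{key[0]},{key[1]}]"][c_idx, k] = delta[key]
                k += 1
        errstate.__exit__(None, None, None)

    acceptance = {
        name: (tot / n if n else np.nan) for name, (tot, n) in acc_tot.items() if n
    }
    return PosteriorDraws(kept, config, acceptance)


# ---------------------------------------------------------------------------
# Estimators


class BaselineOccupancy(BaseEstimator):
    """Hierarchical baseline permanence/recolonization model (control data).

    Parameters
    ----------
    config : MCMCConfig, optional
        Chain settings; the protocol default is 5 chains x 5000 steps.
    freeze_hyperparams : tuple of 4 floats, optional
        Fix (alpha1, beta1, alpha2, beta2) for every group instead of
        sampling them; ``(1, 1, 1, 1)`` gives independent uniform priors
        per genus, which is the configuration checked against brute-force
        oracles.
    drop_all_zero : bool
        Drop genera never observed in the panel before fitting.

    Attributes
    ----------
    draws_ : PosteriorDraws
    groups_ : list of fitted group ids
    genera_ : list of fitted genus names
    """

    def __init__(self, config: MCMCConfig | None = None,
                 freeze_hyperparams: tuple | None = None,
                 drop_all_zero: bool = False):
        self.config = config
        self.freeze_hyperparams = freeze_hyperparams
        self.drop_all_zero = drop_all_zero

    def fit(self, panel: OccurrencePanel, expected_groups: Sequence[int] | None = None):
        config = self.config or MCMCConfig()
        if (panel.series_meta["frequency"] != "C").any():
            raise ValueError("baseline fit expects a control-only panel; "
                             "use OccurrencePanel.control_only()")
        if self.drop_all_zero:
            zeros = set(panel.all_zero_genera())
            keep = np.array([g not in zeros for g in panel.genera])
            panel = OccurrencePanel(
                occurrences=panel.occurrences[keep],
                genera=[g for g in panel.genera if g not in zeros],
                series_meta=panel.series_meta,
                occasion_days=panel.occasion_days,
                genus_group=panel.genus_group,
            )
        stats = _PanelStats(panel, ["C"])
        if expected_groups is not None:
            empty = sorted(set(expected_groups) - set(stats.groups))
            if empty:
                raise ValueError(f"groups with zero genera: {empty}")
        frozen = tuple(self.freeze_hyperparams) if self.freeze_hyperparams is not None else None
        self.draws_ = _run_occupancy_sampler(stats, config, frozen, sample_delta=False)
        self.groups_ = stats.groups
        self.genera_ = stats.genera
        self.group_of_ = stats.group_of
        return self

    def group_summaries(self, level: float = 0.95) -> dict[int, dict[str, CredibleSummary]]:
        """Per-group posterior summaries of the mean theta and psi.

        With sampled hyperparameters these are the Beta-mean draws
        alpha/(alpha+beta); with frozen hyperparameters, the group-pooled
        genus draws.
        """
        out: dict[int, dict[str, CredibleSummary]] = {}
        for g in self.groups_:
            if f"theta_group[{g}]" in self.draws_:
                th = self.draws_.pooled(f"theta_group[{g}]")
                ps = self.draws_.pooled(f"psi_group[{g}]")
            else:
                rows = [i for i, gg in enumerate(self.group_of_) if gg == g]
                th = np.concatenate([self.draws_.pooled(f"theta[{self.genera_[i]}]") for i in rows])
                ps = np.concatenate([self.draws_.pooled(f"psi[{self.genera_[i]}]") for i in rows])
            from .panel import credible_interval

            out[g] = {"theta": credible_interval(th, level), "psi": credible_interval(ps, level)}
        return out


class TreatmentOccupancy(BaseEstimator):
    """Baseline model plus per-cell permanence deviations delta_{k,g}.

    By default the genus parameters, hyperparameters and deviations are
    fitted jointly.  With ``conditional=True`` the genus-level theta/psi are
    plugged in from a fitted :class:`BaselineOccupancy` (posterior means)
    and only the deviations are sampled.  ``freeze_delta=True`` pins every
    deviation at the control value 1, reducing the model to the baseline.
    """

    def __init__(self, config: MCMCConfig | None = None,
                 freeze_hyperparams: tuple | None = None,
                 freeze_delta: bool = False,
                 conditional: bool = False):
        self.config = config
        self.freeze_hyperparams = freeze_hyperparams
        self.freeze_delta = freeze_delta
        self.conditional = conditional

    def fit(self, panel: OccurrencePanel, baseline: BaselineOccupancy | None = None):
        config = self.config or MCMCConfig()
        labels = set(panel.series_cells())
        unknown = labels - {"C"} - set(TREATMENT_CELLS)
        if unknown:
            raise ValueError(f"unknown treatment cells: {sorted(unknown)}")
        trt = [c for c in TREATMENT_CELLS if c in labels]
        if not trt and not self.freeze_delta:
            raise ValueError("panel contains only control series; "
                             "nothing to estimate a deviation from")
        cells = ["C"] + trt
        stats = _PanelStats(panel, cells)
        fixed = None
        if self.conditional:
            if baseline is None:
                raise ValueError("conditional fitting needs a fitted baseline")
            summ = baseline.draws_.summary()
            theta = np.array([summ.loc[f"theta[{g}]", "mean"] for g in stats.genera])
            psi = np.array([summ.loc[f"psi[{g}]", "mean"] for g in stats.genera])
            fixed = (theta, psi)
        frozen = tuple(self.freeze_hyperparams) if self.freeze_hyperparams is not None else None
        self.draws_ = _run_occupancy_sampler(
            stats, config, frozen, sample_delta=not self.freeze_delta, fixed_genus_params=fixed
        )
        self.groups_ = stats.groups
        self.genera_ = stats.genera
        self.group_of_ = stats.group_of
        self.cells_ = trt
        return self

    def permanence_summaries(self, level: float = 0.95):
        """Control and per-cell treatment permanence CIs per group.

        The treatment-cell permanence is the per-draw product
        clamp(psi_g * delta_{k,g}, 0, 1) of the group permanence mean and
        the cell deviation.
        """
        from .panel import credible_interval

        out: dict[int, dict[str, CredibleSummary]] = {}
        for g in self.groups_:
            if f"psi_group[{g}]" in self.draws_:
                psi = self.draws_.pooled(f"psi_group[{g}]")
            else:
                rows = [i for i, gg in enumerate(self.group_of_) if gg == g]
                psi = np.mean(
                    [self.draws_.pooled(f"psi[{self.genera_[i]}]") for i in rows], axis=0
                )
            entry = {"C": credible_interval(psi, level)}
            for cell in self.cells_:
                d = self.draws_.pooled(f"delta[{cell},{g}]")
                entry[cell] = credible_interval(np.clip(psi * d, 0.0, 1.0), level)
            out[g] = entry
        return out


class ImmediateEffect(BaseEstimator):
    """Before/after binomial model of the immediate disturbance effect.

    For each genus i in group g, ``B_i ~ Binomial(n, b_g)`` and
    ``A_i ~ Binomial(n, clamp(b_g * e_g))`` with a flat Beta(1, 1) prior on
    b_g and a vague Gamma(0.001, 0.001) prior on the multiplier e_g.  The
    effect is reported on the ratio scale (draws of e_g) and, for
    comparability with exp-transformed reports, as exp(e_g).
    """

    def __init__(self, config: MCMCConfig | None = None, n_trials: int = 5):
        self.config = config
        self.n_trials = n_trials

    def fit(self, before: Sequence[int], after: Sequence[int], groups: Sequence[int]):
        config = self.config or MCMCConfig()
        B = np.asarray(before, dtype=int)
        A = np.asarray(after, dtype=int)
        groups = np.asarray(groups, dtype=int)
        n = int(self.n_trials)
        if n < 1:
            raise ValueError("n_trials must be >= 1")
        if B.shape != A.shape or B.shape != groups.shape:
            raise ValueError("before, after and groups must have equal length")
        if (B < 0).any() or (A < 0).any() or (B > n).any() or (A > n).any():
            raise ValueError(f"counts must lie in 0..{n}")

        gids = sorted(set(groups.tolist()))
        stats = {
            g: (int((groups == g).sum()), int(B[groups == g].sum()), int(A[groups == g].sum()))
            for g in gids
        }

        def local_lp(g, b, e):
            m, sb, sa = stats[g]
            a = _clamp(b * e)
            lp = sb * np.log(b) + (m * n - sb) * np.log1p(-b)
            lp += sa * np.log(a) + (m * n - sa) * np.log1p(-a)
            lp += _log_gamma_pdf(e, _GAMMA_SHAPE, _GAMMA_RATE)
            return lp

        ss = np.random.SeedSequence(config.seed)
        n_keep = config.draws_per_chain
        kept = {f"{p}[{g}]": np.empty((config.n_chains, n_keep)) for g in gids for p in ("b", "e")}
        acc = {"b": [0.0, 0], "e": [0.0, 0]}
        errstate = np.errstate(divide="ignore", invalid="ignore")
        errstate.__enter__()
        for c_idx, seed in enumerate(ss.spawn(config.n_chains)):
            rng = np.random.default_rng(seed)
            b = {g: _clamp((stats[g][1] + 1) / (stats[g][0] * n + 2)) for g in gids}
            e = {g: max(0.05, min((stats[g][2] + 1.0) / (stats[g][1] + 1.0), 20.0)) for g in gids}
            sb = {g: _AdaptiveScale(config.step_logit) for g in gids}
            se = {g: _AdaptiveScale(config.step_log) for g in gids}
            k = 0
            for it in range(config.total_steps):
                burn = it < config.burn_in
                for g in gids:
                    # b_g on the logit scale
                    z = _logit(b[g]) + sb[g].value * rng.standard_normal()
                    b_new = _expit(z)
                    ljac = (np.log(b_new) + np.log1p(-b_new)) - (np.log(b[g]) + np.log1p(-b[g]))
                    a = np.log(rng.random()) < local_lp(g, b_new, e[g]) - local_lp(g, b[g], e[g]) + ljac
                    if a:
                        b[g] = b_new
                    sb[g].record(a)
                    if not burn:
                        acc["b"][0] += a
                        acc["b"][1] += 1
                    # e_g on the log scale
                    e_new = e[g] * np.exp(se[g].value * rng.standard_normal())
                    ljac = np.log(e_new) - np.log(e[g])
                    a = np.log(rng.random()) < local_lp(g, b[g], e_new) - local_lp(g, b[g], e[g]) + ljac
                    if a:
                        e[g] = e_new
                    se[g].record(a)
                    if not burn:
                        acc["e"][0] += a
                        acc["e"][1] += 1
                if burn:
                    for g in gids:
                        sb[g].maybe_adapt()
                        se[g].maybe_adapt()
                elif (it - config.burn_in) % config.thin == 0 and k < n_keep:
                    for g in gids:
                        kept[f"b[{g}]"][c_idx, k] = b[g]
                        kept[f"e[{g}]"][c_idx, k] = e[g]
                    k += 1
        errstate.__exit__(None, None, None)

        draws = dict(kept)
        for g in gids:
            draws[f"effect_exp[{g}]"] = np.exp(kept[f"e[{g}]"])
        self.draws_ = PosteriorDraws(
            draws, config, {k: v[0] / v[1] for k, v in acc.items() if v[1]}
        )
        self.groups_ = gids
        return self


# ---------------------------------------------------------------------------
# Functional wrappers


def fit_baseline(panel: OccurrencePanel, config: MCMCConfig | None = None, **kwargs) -> BaselineOccupancy:
    return BaselineOccupancy(config=config, **kwargs).fit(panel)


def fit_immediate(
    before: Sequence[int],
    after: Sequence[int],
    n: int,
    groups: Sequence[int],
    config: MCMCConfig | None = None,
) -> ImmediateEffect:
    return ImmediateEffect(config=config, n_trials=n).fit(before, after, groups)


def fit_treatment(
    panel: OccurrencePanel,
    config: MCMCConfig | None = None,
    baseline: BaselineOccupancy | None = None,
    **kwargs,
) -> TreatmentOccupancy:
    return TreatmentOccupancy(config=config, **kwargs).fit(panel, baseline=baseline)


# ---------------------------------------------------------------------------
# Hypothesis report


def _in_band(value: float, level: str) -> bool:
    lo, hi = HYPOTHESIS_BANDS[level]
    return lo <= value <= hi if hi == 1.0 else lo <= value < hi


def hypothesis_check(
    baseline_summaries: Mapping[int, Mapping[str, CredibleSummary]],
    trait_table: Sequence[TraitRecord],
) -> dict[int, str]:
    """Compare fitted group means with the trait-based expectations.

    For each group, checks whether the posterior means of permanence and
    recolonization fall inside their hypothesized ordinal bands, returning
    ``supported`` (both), ``partial`` (one) or ``unsupported`` (neither).
    """
    from .panel import group_hypotheses

    levels = group_hypotheses(trait_table)
    verdicts = {}
    for g, summ in baseline_summaries.items():
        if g not in levels:
            raise KeyError(f"no hypothesis levels for group {g}")
        psi_level, theta_level = levels[g]
        hits = int(_in_band(summ["psi"].mean, psi_level)) + int(
            _in_band(summ["theta"].mean, theta_level)
        )
        verdicts[g] = {2: "supported", 1: "partial", 0: "unsupported"}[hits]
    return verdicts
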