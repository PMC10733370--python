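"""Feedforward integration model of corticofugal drive onto the NOT-DTN.

A single postsynaptic node receives N = 100 cortical neurons split into four
direction-preference groups (TN, UP, NT, DN).  Each neuron contributes its
group's firing-rate template u_g(t) through a uniform synaptic weight
w = 0.005; the synaptic current obeys the leaky integrator

    tau dI_s/dt = -I_s + sum_b w_b u_b(t),      tau = 3.9 ms (AMPA decay),

and the charge C is the integral of I_s over a 3.5 s window from stimulus
onset.  Plasticity multiplies each group's rate by (1 + dR_g); the model
output is the fractional charge change dC = (C_post - C_pre)/C_pre.

Because the ODE is linear, dC is an exact affine function of the group
plasticity strengths with coefficients equal to each group's share of the
pre-potentiation charge — the analytic identities the tests verify.

The integrator advances with the exact solution for piecewise-linear input,
so refining the step does not change the result beyond round-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import InvalidParameterError, MissingGroupError
from .synthetic import GROUPS_4DIR, PopulationComposition

DEFAULT_TAU_S = 0.0039
DEFAULT_WEIGHT = 0.005
DEFAULT_N_NEURONS = 100
DEFAULT_CHARGE_WINDOW_S = 3.5


@dataclass(frozen=True)
class ModelConfig:
    tau_s: float = DEFAULT_TAU_S
    w: float = DEFAULT_WEIGHT
    n_neurons: int = DEFAULT_N_NEURONS
    charge_window_s: float = DEFAULT_CHARGE_WINDOW_S
    dt_s: float = 0.0005  # 0.5 ms: divides both the 1 s baseline and the window

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise InvalidParameterError("tau_s must be positive")
        if self.charge_window_s <= 0:
            raise InvalidParameterError("charge_window_s must be positive")
        if self.dt_s > self.tau_s / 5:
            raise InvalidParameterError("dt_s must be <= tau_s / 5")


@dataclass
class RateTemplate:
    """Baseline-subtracted firing-rate time course of one direction group."""

    group: str
    time_s: np.ndarray  # t = 0 at stimulus onset
    rate_pre: np.ndarray
    rate_post: np.ndarray
    plasticity_strength: float = 0.0

    def with_plasticity(self, strength: float) -> "RateTemplate":
        return RateTemplate(
            group=self.group,
            time_s=self.time_s,
            rate_pre=self.rate_pre,
            rate_post=self.rate_pre * (1.0 + strength),
            plasticity_strength=strength,
        )


@dataclass
class CurrentTrace:
    time_s: np.ndarray
    current: np.ndarray
    charge: float
    config: ModelConfig


@dataclass(frozen=True)
class ScenarioSpec:
    """Which population supplies each circuit feature of a simulation."""

    composition_source: str = "notdtn"  # notdtn | midbrain | custom
    response_source: str = "notdtn"  # notdtn | midbrain
    plasticity_source: str = "differential"  # differential | uniform | swapped | midbrain
    custom_fractions: Mapping[str, float] | None = None

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        from pathlib import Path

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class TemplateBank:
    """Per-population templates, compositions and plasticity maps used by the
    scenario machinery ('notdtn' and 'midbrain' populations)."""

    templates: dict  # population -> {group -> RateTemplate}
    compositions: dict  # population -> PopulationComposition
    plasticity: dict  # population -> {group -> delta_r}


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

def build_rate_templates(
    rates: np.ndarray,
    time_s: np.ndarray,
    groups: Sequence[str],
    group_plasticity: Mapping[str, float],
    population_mean_rate: float,
    pref_rates: Sequence[float] | None = None,
) -> dict[str, RateTemplate]:
    """Group firing-rate templates from per-neuron deconvolved rate traces.

    ``rates`` is (n_neurons, n_t), responses to the temporo-nasal probe;
    ``time_s`` has t = 0 at stimulus onset.  Each neuron's trace is
    normalized to its preferred-direction response (``pref_rates``, one
    scalar per neuron; defaults to the trace's own peak), averaged within
    its group, scaled by a single common factor so the group-size-weighted
    mean of the templates' post-onset mean rates equals
    ``population_mean_rate``, and baseline-subtracted (mean of the
    pre-onset samples).  rate_post = rate_pre * (1 + dR_group).

    Normalizing to the preferred direction (rather than each trace's own
    peak) is what lets direction-selectivity strength shape the model: in a
    weakly selective population the non-TN groups retain large normalized
    responses to the TN probe.
    """
    rates = np.asarray(rates, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    groups = list(groups)
    if rates.shape[0] != len(groups):
        raise InvalidParameterError("one group label per neuron required")
    if pref_rates is None:
        norms = rates.max(axis=1)
    else:
        norms = np.asarray(pref_rates, dtype=float)
        if norms.shape != (rates.shape[0],):
            raise InvalidParameterError("one preferred-direction rate per neuron")
    raw: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for g in GROUPS_4DIR:
        members = [i for i, gg in enumerate(groups) if gg == g]
        if not members:
            raise MissingGroupError(f"group {g} has no neurons")
        normed = [rates[i] / norms[i] for i in members if norms[i] > 0]
        if not normed:
            raise MissingGroupError(f"group {g} has no neurons with positive rates")
        raw[g] = np.mean(normed, axis=0)
        counts[g] = len(members)
    post_onset = time_s >= 0
    weighted_mean = sum(
        counts[g] * raw[g][post_onset].mean() for g in GROUPS_4DIR
    ) / sum(counts.values())
    scale = population_mean_rate / weighted_mean if weighted_mean > 0 else 0.0
    templates = {}
    pre_onset = time_s < 0
    for g in GROUPS_4DIR:
        u = raw[g] * scale
        if pre_onset.any():
            u = u - u[pre_onset].mean()
        strength = float(group_plasticity[g])
        templates[g] = RateTemplate(
            group=g,
            time_s=time_s,
            rate_pre=u,
            rate_post=u * (1.0 + strength),
            plasticity_strength=strength,
        )
    return templates


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _integrate_linear_ode(
    t_in: np.ndarray, u_in: np.ndarray, tau: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution of tau dI/dt = -I + U(t) for piecewise-linear U,
    I(t_in[0]) = 0, advanced on a uniform grid of step ``dt``."""
    n = int(np.floor((t_in[-1] - t_in[0]) / dt + 1e-9)) + 1
    t = t_in[0] + dt * np.arange(n)
    u = np.interp(t, t_in, u_in)
    decay = np.exp(-dt / tau)
    current = np.empty(n)
    current[0] = 0.0
    # on [t_k, t_k+dt]: U(s) = a + b s  ->  I = (I0 - a + tau b) e^{-s/tau} + a + b s - tau b
    b = np.diff(u) / dt
    a = u[:-1]
    for k in range(n - 1):
        current[k + 1] = (
            (current[k] - a[k] + tau * b[k]) * decay + a[k] + b[k] * dt - tau * b[k]
        )
    return t, current


def _charge_exact(
    t: np.ndarray,
    current: np.ndarray,
    u: np.ndarray,
    tau: float,
    w0: float,
    w1: float,
) -> float:
    """Analytic integral of the current over [w0, w1].

    Uses the closed-form solution on each step (input linear, current a sum
    of exponential and linear terms), so the charge is independent of the
    integration step beyond round-off.
    """
    dt = t[1] - t[0]
    b = np.diff(u) / dt
    a = u[:-1]
    c = current[:-1] - a + tau * b
    # local integration bounds within each step
    s0 = np.clip(w0 - t[:-1], 0.0, dt)
    s1 = np.clip(w1 - t[:-1], 0.0, dt)
    ds = s1 - s0
    seg = (
        tau * c * (np.exp(-s0 / tau) - np.exp(-s1 / tau))
        + (a - tau * b) * ds
        + 0.5 * b * (s1**2 - s0**2)
    )
    return float(seg.sum())


def simulate_current(
    templates: Mapping[str, RateTemplate],
    composition: PopulationComposition,
    config: ModelConfig = ModelConfig(),
    phase: str = "pre",
) -> CurrentTrace:
    """Integrate the synaptic current driven by the grouped population.

    Total input is sum over groups of count_g * w * u_g(t), counts from the
    composition by largest-remainder rounding (they sum to ``n_neurons``).
    Charge = integral of I_s over [0, charge_window_s], evaluated with the
    per-step closed form so it does not depend on the solver step.
    """
    if phase not in ("pre", "post"):
        raise InvalidParameterError("phase must be 'pre' or 'post'")
    counts = PopulationComposition(
        group_fractions=composition.group_fractions, n_neurons=config.n_neurons
    ).counts()
    ref = None
    total = None
    for g, count in counts.items():
        if g not in templates:
            raise MissingGroupError(f"no template for group {g}")
        tpl = templates[g]
        if ref is None:
            ref = tpl.time_s
            total = np.zeros_like(ref)
        elif len(tpl.time_s) != len(ref) or not np.allclose(tpl.time_s, ref):
            raise InvalidParameterError("templates must share one time grid")
        u = tpl.rate_pre if phase == "pre" else tpl.rate_post
        total = total + count * config.w * u
    t, current = _integrate_linear_ode(ref, total, config.tau_s, config.dt_s)
    if t[-1] < config.charge_window_s - 1e-12 or t[0] > 1e-12:
        raise InvalidParameterError("charge window not covered by the template grid")
    u_grid = np.interp(t, ref, total)
    charge = _charge_exact(t, current, u_grid, config.tau_s, 0.0, config.charge_window_s)
    return CurrentTrace(time_s=t, current=current, charge=charge, config=config)


def delta_charge(c_pre: float, c_post: float) -> float:
    """Fractional charge change dC = (C_post - C_pre)/C_pre (x100 = percent)."""
    if c_pre <= 0:
        raise InvalidParameterError("c_pre must be positive")
    return (c_post - c_pre) / c_pre


# ---------------------------------------------------------------------------
# Scenarios and sweeps
# ---------------------------------------------------------------------------

def _resolve_plasticity(spec: ScenarioSpec, bank: TemplateBank) -> dict[str, float]:
    base = dict(bank.plasticity[spec.response_source])
    src = spec.plasticity_source
    if src == "differential":
        return base
    if src == "uniform":
        mean = float(np.mean([base[g] for g in GROUPS_4DIR]))
        return {g: mean for g in GROUPS_4DIR}
    if src == "swapped":
        out = dict(base)
        out["TN"], out["NT"] = base["NT"], base["TN"]
        return out
    if src == "midbrain":
        return dict(bank.plasticity["midbrain"])
    raise InvalidParameterError(f"unknown plasticity source {src!r}")


def _resolve_composition(spec: ScenarioSpec, bank: TemplateBank, config: ModelConfig):
    if spec.composition_source == "custom":
        if spec.custom_fractions is None:
            raise InvalidParameterError("custom composition requires custom_fractions")
        return PopulationComposition(
            group_fractions=spec.custom_fractions, n_neurons=config.n_neurons
        )
    try:
        return bank.compositions[spec.composition_source]
    except KeyError as err:
        raise InvalidParameterError(
            f"unknown composition source {spec.composition_source!r}"
        ) from err


def run_scenario(
    spec: ScenarioSpec, bank: TemplateBank, config: ModelConfig = ModelConfig()
) -> float:
    """Assemble composition, responses, and plasticity from the named sources
    and return the resulting fractional charge change dC."""
    if spec.response_source not in bank.templates:
        raise InvalidParameterError(f"unknown response source {spec.response_source!r}")
    composition = _resolve_composition(spec, bank, config)
    strengths = _resolve_plasticity(spec, bank)
    templates = {
        g: bank.templates[spec.response_source][g].with_plasticity(strengths[g])
        for g in GROUPS_4DIR
    }
    c_pre = simulate_current(templates, composition, config, "pre").charge
    c_post = simulate_current(templates, composition, config, "post").charge
    return delta_charge(c_pre, c_post)


def _tn_fraction_composition(
    base: PopulationComposition, fraction: float, n_neurons: int
) -> PopulationComposition:
    """TN holds ``fraction``; the remainder is split among UP/NT/DN in
    proportion to their original fractions."""
    if not 0 <= fraction <= 1:
        raise InvalidParameterError("fraction must lie in [0, 1]")
    others = {g: f for g, f in base.group_fractions.items() if g != "TN"}
    rest = sum(others.values())
    fr = {"TN": fraction}
    for g, f in others.items():
        fr[g] = (1.0 - fraction) * (f / rest) if rest > 0 else (1.0 - fraction) / 3
    return PopulationComposition(group_fractions=fr, n_neurons=n_neurons)


def sweep_tn_fraction(
    fractions: Sequence[float],
    bank: TemplateBank,
    config: ModelConfig = ModelConfig(),
    *,
    response_source: str = "notdtn",
    plasticity_source: str = "differential",
) -> np.ndarray:
    """dC as a function of the temporo-nasal fraction of the population."""
    base = bank.compositions[response_source]
    spec = ScenarioSpec(
        composition_source="custom",
        response_source=response_source,
        plasticity_source=plasticity_source,
    )
    strengths = _resolve_plasticity(spec, bank)
    templates = {
        g: bank.templates[response_source][g].with_plasticity(strengths[g])
        for g in GROUPS_4DIR
    }
    out = []
    for f in fractions:
        comp = _tn_fraction_composition(base, float(f), config.n_neurons)
        c_pre = simulate_current(templates, comp, config, "pre").charge
        c_post = simulate_current(templates, comp, config, "post").charge
        out.append(delta_charge(c_pre, c_post))
    return np.asarray(out)


def sweep_tn_plasticity(
    strengths: Sequence[float],
    bank: TemplateBank,
    config: ModelConfig = ModelConfig(),
    *,
    response_source: str = "notdtn",
) -> np.ndarray:
    """dC as a function of the TN group's plasticity strength, all else fixed."""
    base = dict(bank.plasticity[response_source])
    comp = bank.compositions[response_source]
    out = []
    for s in strengths:
        if s <= -1:
            raise InvalidParameterError("plasticity strength must exceed -1")
        pl = dict(base)
        pl["TN"] = float(s)
        templates = {
            g: bank.templates[response_source][g].with_plasticity(pl[g])
            for g in GROUPS_4DIR
        }
        c_pre = simulate_current(templates, comp, config, "pre").charge
        c_post = simulate_current(templates, comp, config, "post").charge
        out.append(delta_charge(c_pre, c_post))
    return np.asarray(out)


def synthetic_bank(
    seed: int = 0,
    *,
    noise_sd: float = 0.0,
    n_neurons: int = 60,
    n_trials: int = 6,
    population_mean_rate: float = 10.0,
    notdtn_fractions: Mapping[str, float] | None = None,
    midbrain_fractions: Mapping[str, float] | None = None,
    notdtn_factors: Mapping[str, float] | None = None,
    midbrain_factors: Mapping[str, float] | None = None,
) -> TemplateBank:
    """Template bank built by running the full calcium pipeline on synthetic
    populations that mimic the two corticofugal projection classes.

    The NOT-DTN-projecting population is temporo-nasally enriched, strongly
    direction selective, with plasticity concentrated in the TN group; the
    midbrain-projecting population is unbiased, weakly selective, with weak
    uniform plasticity.  Pre/post trials are simulated, responses analyzed,
    trial-averaged dF/F at the TN probe deconvolved, group plasticity
    strengths estimated, and rate templates assembled — the same route real
    recordings would take.
    """
    from . import plasticity as pl
    from . import synthetic as syn
    from . import tuning as tn

    notdtn_fractions = notdtn_fractions or {"TN": 0.37, "UP": 0.21, "NT": 0.21, "DN": 0.21}
    midbrain_fractions = midbrain_fractions or {g: 0.25 for g in GROUPS_4DIR}
    notdtn_factors = notdtn_factors or {"TN": 1.4, "UP": 1.1, "NT": 1.05, "DN": 1.1}
    midbrain_factors = midbrain_factors or {g: 1.1 for g in GROUPS_4DIR}
    populations = {
        "notdtn": (notdtn_fractions, notdtn_factors, 0.25),
        "midbrain": (midbrain_fractions, midbrain_factors, 0.6),
    }
    directions = [0.0, 90.0, 180.0, 270.0]
    templates, compositions, strengths = {}, {}, {}
    for k, (pop, (fractions, factors, null_ratio)) in enumerate(populations.items()):
        comp = PopulationComposition(group_fractions=fractions, n_neurons=n_neurons)
        neurons = syn.sample_population(
            comp, seed=seed + k, dir_null_ratio=null_ratio, plasticity_factors=factors
        )
        pre = syn.gen_calcium_trials(
            neurons, directions, n_trials, noise_sd=noise_sd, seed=seed + 10 + k, phase="pre"
        )
        post = syn.gen_calcium_trials(
            neurons, directions, n_trials, noise_sd=noise_sd, seed=seed + 20 + k, phase="post"
        )
        pre_metrics = tn.analyze_population(pre)
        post_metrics = tn.analyze_population(post)
        records = pl.build_plasticity_records(pre_metrics, post_metrics)
        table = pl.group_plasticity_strength(records)
        dr = dict(zip(table["group"], table["mean_delta_r"]))
        for g in GROUPS_4DIR:
            dr.setdefault(g, 0.0)
        # deconvolved firing-rate traces per neuron, all directions
        dff = tn.compute_dff(pre).mean(axis=2)  # (n_neurons, n_stim, n_frames)
        frame_rate = 1.0 / np.diff(pre.frame_times_s).mean()
        all_rates = tn.deconvolve_calcium(dff, pre.kernel_tau_s, frame_rate)
        rates = all_rates[:, 0, :]  # TN probe
        prefs = pre_metrics["sampled_pref_deg"].to_numpy(float)
        groups = [pl.classify_group(p) if np.isfinite(p) else "TN" for p in prefs]
        # normalizer: peak deconvolved rate at each neuron's preferred direction
        dir_index = {d: j for j, d in enumerate(pre.directions_deg)}
        pref_rates = np.array(
            [
                all_rates[i, dir_index.get(p % 360.0, 0)].max()
                for i, p in enumerate(prefs)
            ]
        )
        templates[pop] = build_rate_templates(
            rates,
            pre.frame_times_s - pre.pre_window_s,
            groups,
            dr,
            population_mean_rate,
            pref_rates=pref_rates,
        )
        compositions[pop] = PopulationComposition(
            group_fractions=fractions, n_neurons=DEFAULT_N_NEURONS
        )
        strengths[pop] = {g: float(dr[g]) for g in GROUPS_4DIR}
    return TemplateBank(
        templates=templates, compositions=compositions, plasticity=strengths
    )


def charge_shares(
    templates: Mapping[str, RateTemplate],
    composition: PopulationComposition,
    config: ModelConfig = ModelConfig(),
) -> dict[str, float]:
    """Each group's share of the pre-potentiation charge (they sum to 1);
    the affine coefficients that link dC to the group plasticity strengths."""
    counts = PopulationComposition(
        group_fractions=composition.group_fractions, n_neurons=config.n_neurons
    ).counts()
    charges = {}
    for g in GROUPS_4DIR:
        solo = {
            gg: RateTemplate(
                group=gg,
                time_s=templates[gg].time_s,
                rate_pre=templates[gg].rate_pre if gg == g else np.zeros_like(templates[gg].rate_pre),
                rate_post=templates[gg].rate_pre if gg == g else np.zeros_like(templates[gg].rate_pre),
            )
            for gg in GROUPS_4DIR
        }
        charges[g] = simulate_current(solo, composition, config, "pre").charge
    total = sum(charges.values())
    return {g: c / total for g, c in charges.items()}
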