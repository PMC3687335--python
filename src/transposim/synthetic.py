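"""Seeded synthetic datasets and the stochastic simulation oracle.

Three measurement types are emulated with known ground truth for
estimator-recovery tests:

* electrophoretic mobility-shift (EMSA) dissociation time courses --
  first-order exponential decay of the bound fraction,
* substrate-consumption gel kinetics of a test-tube transposition
  reaction -- pseudo-first-order synapsis read out as the disappearance of
  unreacted substrate (only the singly-occupied half of the substrate
  reacts initially, so the quarter-consumption time approximates the
  synapsis half-time), and
* transposase dose-response colony counts -- a power law ``y = a x^b``
  with ``b = -1`` under assembly-site occlusion.

Measurement noise is multiplicative lognormal (gel, EMSA and colony-count
signals are positive with roughly proportional errors); colony counts can
additionally be Poisson-sampled.  All generators take an integer seed and
are byte-reproducible.

The module also provides an exact event-driven stochastic simulation
(Gillespie) of the naked-end-capture reaction network on small instances,
used as an independent oracle for the deterministic ODE treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .invasion_models import (
    CellContext,
    KineticParameterSet,
    simulate_invitro_reaction,
)

__all__ = [
    "SyntheticDataset",
    "gen_emsa_decay",
    "gen_dose_response",
    "gen_gel_timecourse",
    "stochastic_oracle",
    "StochasticEnsemble",
]


@dataclass(frozen=True)
class SyntheticDataset:
    """One synthetic measurement with its generating truth."""

    kind: str  # emsa_decay | gel_timecourse | dose_response
    design: np.ndarray  # sampled times (s) or doses
    observations: np.ndarray
    truth: dict
    seed: int
    noise_cv: float

    def to_frame(self):
        import pandas as pd

        x_name = "dose" if self.kind == "dose_response" else "time"
        return pd.DataFrame({x_name: self.design, "observation": self.observations})


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested coefficient of variation."""
    if cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def gen_emsa_decay(
    k_off: float,
    times,
    noise_cv: float = 0.10,
    seed: int = 0,
) -> SyntheticDataset:
    """Bound fraction ``exp(-k_off t)`` of a challenged protein-DNA complex.

    Emulates a competition EMSA in which pre-formed complexes are chased
    with excess unlabelled binding site, so rebinding is negligible and
    the labelled bound fraction decays with the dissociation rate
    constant.
    """
    if not k_off > 0:
        raise ValueError("k_off must be positive")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    rng = np.random.default_rng(seed)
    clean = np.exp(-k_off * times)
    obs = clean * _lognormal_factors(rng, noise_cv, times.size)
    return SyntheticDataset(
        kind="emsa_decay",
        design=times,
        observations=obs,
        truth={"k_off": k_off},
        seed=seed,
        noise_cv=noise_cv,
    )


def gen_dose_response(
    a: float,
    b: float,
    doses,
    noise_cv: float = 0.20,
    seed: int = 0,
    poisson: bool = False,
) -> SyntheticDataset:
    """Colony counts following ``y = a * dose^b`` with multiplicative noise.

    Under assembly-site occlusion the transposition rate is inversely
    proportional to the transposase dose, so the generating truth for that
    mechanism is ``b = -1``.  ``poisson=True`` additionally draws integer
    counts from a Poisson with the noisy mean.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    clean = a * doses**b
    obs = clean * _lognormal_factors(rng, noise_cv, doses.size)
    if poisson:
        obs = rng.poisson(obs).astype(float)
    return SyntheticDataset(
        kind="dose_response",
        design=doses,
        observations=obs,
        truth={"a": a, "b": b},
        seed=seed,
        noise_cv=noise_cv,
    )


def gen_gel_timecourse(
    params: KineticParameterSet,
    times,
    substrate_M: float = 6.7e-9,
    transposase_M: float = 6.7e-9,
    noise_cv: float = 0.10,
    seed: int = 0,
    binding_preequilibrated: bool = True,
) -> SyntheticDataset:
    """Remaining-substrate fraction of a test-tube transposition reaction.

    The clean signal is produced by the naked-end-capture ODE without
    copy-number coupling at the given substrate and transposase (dimer)
    concentrations; substrate is counted as consumed once it has synapsed
    (the first nick follows synapsis immediately).  By default binding is
    pre-equilibrated before time zero (the pre-incubation stage of the
    assay, before the catalytic metal ion is added), so at the optimal
    ratio of one dimer per transposon only the singly-occupied half of the
    substrate can react at first and the quarter-consumption time
    approximates the synapsis half-time ln2 / k2.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    rng = np.random.default_rng(seed)
    _, y = simulate_invitro_reaction(
        params,
        substrate_M,
        transposase_M,
        times,
        binding_preequilibrated=binding_preequilibrated,
    )
    consumed = (y[4] + y[5]) / substrate_M  # synapsed + matured
    remaining = np.clip(1.0 - consumed, 0.0, None)
    obs = remaining * _lognormal_factors(rng, noise_cv, times.size)
    return SyntheticDataset(
        kind="gel_timecourse",
        design=times,
        observations=obs,
        truth={
            "k2": params.k2,
            "substrate_M": substrate_M,
            "transposase_M": transposase_M,
        },
        seed=seed,
        noise_cv=noise_cv,
    )


# ---------------------------------------------------------------------------
# exact stochastic oracle


@dataclass
class StochasticEnsemble:
    """Checkpointed ensemble of exact stochastic runs."""

    times: np.ndarray  # checkpoint times (s)
    species: tuple[str, ...]
    trajectories: np.ndarray  # (n_runs, n_checkpoints, n_species)
    seed: int

    @property
    def mean(self) -> np.ndarray:
        return self.trajectories.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        n = self.trajectories.shape[0]
        return self.trajectories.std(axis=0, ddof=1) / math.sqrt(n)

    def copy_number(self) -> np.ndarray:
        """Per-run copy number at the checkpoints (transposon pools summed)."""
        pool_idx = [i for i, s in enumerate(self.species) if s in ("U", "S", "D", "P")]
        return self.trajectories[:, :, pool_idx].sum(axis=2)


_MAX_EVENTS = 2_000_000


def stochastic_oracle(
    params: KineticParameterSet,
    ctx: CellContext,
    checkpoint_times,
    n_runs: int = 200,
    seed: int = 0,
    n0: int = 1,
) -> StochasticEnsemble:
    """Exact event-driven simulation of the naked-end-capture network.

    Integer-count Gillespie sampling of the same reactions as the ODE:
    non-specific exchange, sequential end binding with the two-end
    statistical factors, synapsis, reversal and maturation.  Each
    maturation event realises the geometric copy flux as a Bernoulli draw
    with probability ``|ln efficiency|`` (gain for efficiency > 1, loss of
    the completing copy for efficiency < 1), so the ensemble mean matches
    the deterministic flux ``ln(efficiency) * k3 * P``.  New copies express
    their transposase instantly.

    Only small instances are accepted (copy number <= 50 and at most ~1e4
    transposase molecules); larger systems are the ODE solver's job.
    """
    checkpoint_times = np.asarray(checkpoint_times, dtype=float)
    if n0 > 50 or ctx.expression_per_copy * n0 > 1e4:
        raise ValueError(
            "instance too large for exact sampling: keep n0 <= 50 and "
            "expression_per_copy * n0 <= 1e4, or use the ODE engine"
        )
    p = params
    c0 = ctx.per_pair_rate(p.k0)
    c1 = ctx.per_pair_rate(p.k1)
    s_ns = ctx.n_nonspecific
    g = math.log(ctx.efficiency)
    p_gain = abs(g)
    if p_gain > 1:
        raise ValueError("efficiency outside (1/e, e): Bernoulli realisation undefined")
    E = ctx.expression_per_copy
    species = ("T_free", "T_nsb", "U", "S", "D", "P")
    rng = np.random.default_rng(seed)
    n_cp = checkpoint_times.size
    out = np.zeros((n_runs, n_cp, 6))
    t_end = float(checkpoint_times.max())
    for run in range(n_runs):
        Tf = float(E * n0)
        Tn = 0.0
        U, S, D, P = float(n0), 0.0, 0.0, 0.0
        t = 0.0
        cp = 0
        events = 0
        while True:
            a = (
                c0 * Tf * s_ns,  # 0: non-specific binding
                p.k_minus0 * Tn,  # 1: non-specific release
                2 * c1 * Tf * U,  # 2: first-end binding
                p.k_minus1 * S,  # 3: first-end release
                c1 * Tf * S,  # 4: second-end binding (occlusion)
                2 * p.k_minus1 * D,  # 5: second-end release
                p.k2 * S,  # 6: synapsis
                p.k_minus2 * P,  # 7: synapsis reversal
                p.k3 * P,  # 8: maturation
            )
            a_tot = sum(a)
            t_next = t + (rng.exponential(1.0 / a_tot) if a_tot > 0 else math.inf)
            while cp < n_cp and checkpoint_times[cp] <= t_next:
                out[run, cp] = (Tf, Tn, U, S, D, P)
                cp += 1
            if cp >= n_cp or t_next > t_end or a_tot == 0:
                break
            t = t_next
            events += 1
            if events > _MAX_EVENTS:
                raise RuntimeError(
                    "event budget exceeded; reduce the instance size or the horizon"
                )
            r = rng.random() * a_tot
            idx = 0
            acc = a[0]
            while acc < r:
                idx += 1
                acc += a[idx]
            if idx == 0:
                Tf -= 1; Tn += 1
            elif idx == 1:
                Tn -= 1; Tf += 1
            elif idx == 2:
                U -= 1; S += 1; Tf -= 1
            elif idx == 3:
                S -= 1; U += 1; Tf += 1
            elif idx == 4:
                S -= 1; D += 1; Tf -= 1
            elif idx == 5:
                D -= 1; S += 1; Tf += 1
            elif idx == 6:
                S -= 1; P += 1
            elif idx == 7:
                P -= 1; S += 1
            else:  # maturation
                P -= 1
                U += 1
                Tf += 1
                if p_gain > 0 and rng.random() < p_gain:
                    if g > 0:  # gained sibling, expressed instantly
                        U += 1
                        Tf += E
                    else:  # completing copy lost with its expression share
                        U -= 1
                        removed = min(Tf, E)
                        Tf -= removed
                        Tn -= E - removed
    return StochasticEnsemble(
        times=checkpoint_times, species=species, trajectories=out, seed=seed
    )
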