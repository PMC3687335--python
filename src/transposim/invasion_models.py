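"""ODE right-hand sides for genomic invasion under three assembly mechanisms.

Three ways of assembling the paired-ends complex (the transpososome) are
modelled, each coupling transposase-DNA binding kinetics to transposon copy
number in a single well-mixed nucleus:

``snec``
    Synapsis by naked-end capture (mariner-style): the transposase is a
    dimer; a dimer bound to one end captures the *naked* second end.  A
    second dimer on the other end occludes the assembly site, which is the
    assembly-site-occlusion (ASO) route to overproduction inhibition.
``spd``
    Synapsis by protein dimerization (Tn10/Tn5-style): monomers bind each
    end and synapse by dimerizing.  Extra transposase always helps, so the
    mechanism is intrinsically exponential.  Variant hooks model a
    cis-acting transposase and a trans-acting inhibitor.
``deo``
    Dimerization end occlusion: monomers are the active species; free
    monomers form inactive dimers that bind and occlude the ends.

State is kept in molecule counts per nucleus.  Since the two transposon
ends are identical, end-level species are collapsed to unordered
transposon-level pools with statistical factors of two for binding to a
doubly-free transposon and for dissociation from a doubly-occupied one;
this halves the state count with identical dynamics.

Copy number and expression coupling: transposase expression is
instantaneous, so the total transposase is algebraically slaved to
``expression_per_copy * N``.  A completed transposition event multiplies
the completing lineage by the efficiency ``e`` (copies after the event per
copy before it), which in the continuous-flux limit contributes
``ln(e) * k3 * P`` to ``dN/dt``; the transposon re-enters the unbound pool
and its transposase returns to the free pool.  ``ln(e)`` rather than
``e - 1`` makes amplification geometric per event, reproducing the
logarithmic efficiency-rate relationship of the steady state (rate
proportional to log2 of efficiency) and its corollaries: efficiency 1 is
stasis and efficiencies below 1 shrink the copy number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .rate_theory import AVOGADRO

__all__ = [
    "KineticParameterSet",
    "CellContext",
    "KineticModel",
    "SnecModel",
    "SpdModel",
    "DeoModel",
    "build_model",
    "allostery_override",
    "apply_secondary_site",
    "end_occupancy_fractions",
    "simulate_invitro_reaction",
]


@dataclass(frozen=True)
class KineticParameterSet:
    """Rate constants of one assembly mechanism.

    Bimolecular constants (``k0``, ``k1``, ``deo_dimerization_k``) are in
    M^-1 s^-1; all others in s^-1.  Mechanism-specific extras default to
    inactive values so that the same record serves every mechanism.
    """

    k0: float = 9.9e6  # non-specific association
    k_minus0: float = 139.0  # non-specific dissociation
    k1: float = 3.8e8  # end-specific association
    k_minus1: float = 1.2e-2  # end dissociation
    k2: float = 12.7  # synapsis (pseudo-first-order)
    k_minus2: float = 1e-10  # synapsis reversal (effectively irreversible)
    k3: float = 1.4e-3  # cleavage / integration / maturation
    cis_fraction: float = 0.0  # spd: fraction of expression acting in cis
    inhibitor_potency: float = 0.0  # spd: trans inhibitor, fold-activity vs transposase
    secondary_site_affinity_multiplier: float = 0.0  # snec: extra inhibitory site
    deo_dimerization_k: float | None = None  # deo: 2M -> inactive dimer (default k1)
    deo_dimer_end_affinity_multiplier: float = 1.0  # deo: dimer-to-end association factor

    def __post_init__(self) -> None:
        for name in ("k0", "k_minus0", "k1", "k_minus1", "k2", "k_minus2", "k3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.cis_fraction <= 1.0:
            raise ValueError("cis_fraction must lie in [0, 1]")
        if self.inhibitor_potency < 0:
            raise ValueError("inhibitor_potency must be non-negative")
        if self.secondary_site_affinity_multiplier < 0:
            raise ValueError("secondary site affinity multiplier must be non-negative")
        if self.deo_dimer_end_affinity_multiplier < 0:
            raise ValueError("dimer end affinity multiplier must be non-negative")

    # -- presets -----------------------------------------------------------
    @classmethod
    def in_vitro_ideal(cls) -> "KineticParameterSet":
        """Dilute-solution, non-allosteric constants (derived synapsis rate)."""
        return cls()

    @classmethod
    def in_vivo_ideal(cls) -> "KineticParameterSet":
        """Crowded-nucleus, non-allosteric constants."""
        return cls(k0=5.0e6, k1=1.9e8, k2=4.5e-4)

    @classmethod
    def in_vitro_allosteric(cls) -> "KineticParameterSet":
        """Dilute solution with the experimentally estimated k2 and k-1."""
        return cls(k2=9.6e-5, k_minus1=5.8e-4)

    @classmethod
    def in_vivo_allosteric(cls) -> "KineticParameterSet":
        """Crowded nucleus with allosteric second-end penalty folded into k2."""
        return cls(k0=5.0e6, k1=1.9e8, k2=3.4e-9, k_minus1=5.8e-4)

    @property
    def specific_kd(self) -> float:
        """Equilibrium constant for end binding, k-1/k1 (M)."""
        return self.k_minus1 / self.k1


def allostery_override(
    params: KineticParameterSet, k2_new: float, k_minus1_new: float
) -> KineticParameterSet:
    """Replace the idealized synapsis and end-dissociation rates.

    The allosteric interaction between transposase subunits lowers the
    affinity of the developing transpososome for the second end; its
    magnitude is only available from experimental estimates of ``k2`` and
    ``k-1``, which this override installs.
    """
    if not k2_new > 0 or not k_minus1_new > 0:
        raise ValueError("overridden rates must be positive")
    return replace(params, k2=k2_new, k_minus1=k_minus1_new)


def apply_secondary_site(
    params: KineticParameterSet, multiplier: float
) -> KineticParameterSet:
    """Add an inhibitory secondary transposase binding site to each copy.

    The site binds free transposase with ``multiplier * k1`` (dissociation
    ``k-1``) and blocks synapsis while occupied.  ``multiplier = 0``
    reduces exactly to the baseline model.
    """
    if multiplier < 0:
        raise ValueError("secondary-site multiplier must be non-negative")
    return replace(params, secondary_site_affinity_multiplier=multiplier)


@dataclass(frozen=True)
class CellContext:
    """Host-cell quantities the invasion couples to.

    ``efficiency`` is the copies present after one completed transposition
    event per copy before it (2 = excision behind / reintegration ahead of
    a replication fork with donor-site repair; values below 1 mean net
    loss).  ``expression_per_copy`` counts the expressed transposase
    species: dimers for the naked-end-capture mechanism, monomers for the
    protein-dimerization and dimerization-end-occlusion mechanisms.
    """

    nuclear_volume: float = 500.0  # fl == um^3
    genome_size: float = 3.0e9  # bp, haploid
    ploidy: int = 2
    expression_per_copy: float = 500.0
    transposon_length: float = 1287.0  # bp
    efficiency: float = 2.0
    nonspecific_sites: float | None = None  # default ploidy * genome_size

    def __post_init__(self) -> None:
        if not self.nuclear_volume > 0 or not self.genome_size > 0:
            raise ValueError("nuclear volume and genome size must be positive")
        if self.expression_per_copy < 0:
            raise ValueError("expression_per_copy must be non-negative")
        if not 0 < self.efficiency <= math.e:
            # ln(efficiency) is the per-event copy flux; 2 is the biological
            # maximum, the cap at e keeps the returned-transposon flux
            # non-negative.
            raise ValueError("efficiency must lie in (0, e]")

    @property
    def n_nonspecific(self) -> float:
        if self.nonspecific_sites is not None:
            return self.nonspecific_sites
        return self.ploidy * self.genome_size

    @property
    def volume_litres(self) -> float:
        return self.nuclear_volume * 1e-15

    def per_pair_rate(self, k_molar: float) -> float:
        """Bimolecular constant (M^-1 s^-1) -> per molecule-pair rate (s^-1)."""
        return k_molar / (AVOGADRO * self.volume_litres)

    def count_to_molar(self, count: float) -> float:
        return count / (AVOGADRO * self.volume_litres)

    def molar_to_count(self, conc: float) -> float:
        return conc * AVOGADRO * self.volume_litres


def end_occupancy_fractions(conc_free: float, params: KineticParameterSet):
    """Equilibrium (unbound, single, double) occupancy of a two-end transposon.

    At a clamped free-transposase concentration the two identical ends are
    occupied independently with probability ``theta = c/(c + Kd)``, so the
    pool fractions are binomial: ``(1-theta)^2, 2 theta(1-theta), theta^2``.
    The singly-occupied fraction carries the synapsis flux in the
    naked-end-capture mechanism and is maximal at ``c = Kd``.
    """
    if conc_free < 0:
        raise ValueError("concentration must be non-negative")
    theta = conc_free / (conc_free + params.specific_kd)
    return (1.0 - theta) ** 2, 2.0 * theta * (1.0 - theta), theta**2


# ---------------------------------------------------------------------------
# mechanism models


class KineticModel:
    """Shared plumbing: counts, conversions, conservation bookkeeping."""

    species: tuple[str, ...] = ()
    #: indices of the transposon pools (their sum is the copy number N)
    transposon_pools: tuple[int, ...] = ()

    def __init__(self, params: KineticParameterSet, ctx: CellContext):
        self.params = params
        self.ctx = ctx
        self.c0 = ctx.per_pair_rate(params.k0)
        self.c1 = ctx.per_pair_rate(params.k1)
        self.s_ns = ctx.n_nonspecific
        self.log_gain = math.log(ctx.efficiency)

    # -- interface ---------------------------------------------------------
    def rhs(self, t, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def transposase_units(self, y) -> float:
        """Total expressed units (monomers or dimers) tracked by the state."""
        raise NotImplementedError

    def expression_units_per_copy(self) -> float:
        return self.ctx.expression_per_copy

    def completion_flux(self, y) -> float:
        """Total maturation events per second."""
        raise NotImplementedError

    def copy_number(self, y) -> float:
        y = np.asarray(y)
        return float(np.sum(y[..., list(self.transposon_pools)], axis=-1))

    def copy_number_series(self, ys: np.ndarray) -> np.ndarray:
        return ys[list(self.transposon_pools), :].sum(axis=0)

    def initial_state(self, n0: float = 1.0) -> np.ndarray:
        """All transposase free, all transposons fully unbound."""
        raise NotImplementedError

    def conservation_residual(self, y) -> float:
        """Relative deviation of tracked transposase from expression * N."""
        total = self.transposase_units(y)
        expected = self.expression_units_per_copy() * self.copy_number(y)
        if expected == 0:
            return abs(total)
        return abs(total - expected) / expected

    # -- helpers -----------------------------------------------------------
    def _free_fraction(self) -> float:
        """Equilibrium free fraction against the constant non-specific pool."""
        if self.params.k_minus0 == 0:
            return 1.0 if self.c0 * self.s_ns == 0 else 0.0
        return 1.0 / (1.0 + self.c0 * self.s_ns / self.params.k_minus0)


class SnecModel(KineticModel):
    """Naked-end capture (dimeric transposase) with assembly-site occlusion.

    Pools: ``U`` both ends free, ``S`` one end bound by a dimer (the
    productive precursor), ``D`` both ends bound (the occluded OPI state),
    ``P`` the paired-ends complex.  With a secondary inhibitory site each
    pool is split by secondary-site occupancy (suffix ``_b``), and synapsis
    is blocked while the secondary site is occupied.
    """

    def __init__(self, params: KineticParameterSet, ctx: CellContext):
        super().__init__(params, ctx)
        self.secondary = params.secondary_site_affinity_multiplier > 0
        if self.secondary:
            self.species = (
                "T_free", "T_nsb",
                "U", "S", "D", "P",
                "U_b", "S_b", "D_b", "P_b",
            )
            self.transposon_pools = (2, 3, 4, 5, 6, 7, 8, 9)
            self.c_sec = self.c1 * params.secondary_site_affinity_multiplier
        else:
            self.species = ("T_free", "T_nsb", "U", "S", "D", "P")
            self.transposon_pools = (2, 3, 4, 5)

    def initial_state(self, n0: float = 1.0) -> np.ndarray:
        y = np.zeros(len(self.species))
        y[0] = self.ctx.expression_per_copy * n0
        y[2] = n0
        return y

    def transposase_units(self, y) -> float:
        if self.secondary:
            Tf, Tn, U, S, D, P, Ub, Sb, Db, Pb = y
            bound = S + 2 * D + P + (Ub + Sb + Db + Pb) + (Sb + 2 * Db + Pb)
            return float(Tf + Tn + bound)
        Tf, Tn, U, S, D, P = y
        return float(Tf + Tn + S + 2 * D + P)

    def completion_flux(self, y) -> float:
        if self.secondary:
            return self.params.k3 * (y[5] + y[9])
        return self.params.k3 * y[5]

    def rhs(self, t, y):
        p = self.params
        g = self.log_gain
        E = self.ctx.expression_per_copy
        if not self.secondary:
            Tf, Tn, U, S, D, P = y
            ns = self.c0 * Tf * self.s_ns - p.k_minus0 * Tn
            bUS = 2 * self.c1 * Tf * U
            bSU = p.k_minus1 * S
            bSD = self.c1 * Tf * S
            bDS = 2 * p.k_minus1 * D
            syn = p.k2 * S
            rev = p.k_minus2 * P
            comp = p.k3 * P
            dTf = -ns - bUS + bSU - bSD + bDS + comp + E * g * comp
            dTn = ns
            dU = -bUS + bSU + (1 + g) * comp
            dS = bUS - bSU - bSD + bDS - syn + rev
            dD = bSD - bDS
            dP = syn - rev - comp
            return np.array([dTf, dTn, dU, dS, dD, dP])

        Tf, Tn, U, S, D, P, Ub, Sb, Db, Pb = y
        ns = self.c0 * Tf * self.s_ns - p.k_minus0 * Tn
        out = np.zeros(10)
        # secondary-site binding/unbinding moves pool X <-> X_b
        sec_on = self.c_sec * Tf
        sec_off = p.k_minus1
        total_comp = p.k3 * (P + Pb)
        sec_bound_flux = 0.0
        for i, ib in ((2, 6), (3, 7), (4, 8), (5, 9)):
            f_on = sec_on * y[i]
            f_off = sec_off * y[ib]
            out[i] += -f_on + f_off
            out[ib] += f_on - f_off
            sec_bound_flux += f_on - f_off
        for sec_occupied, (iU, iS, iD, iP) in (
            (False, (2, 3, 4, 5)),
            (True, (6, 7, 8, 9)),
        ):
            u, s, d, pe = y[iU], y[iS], y[iD], y[iP]
            bUS = 2 * self.c1 * Tf * u
            bSU = p.k_minus1 * s
            bSD = self.c1 * Tf * s
            bDS = 2 * p.k_minus1 * d
            # an occupied secondary site blocks the S -> P synapsis flux
            syn = 0.0 if sec_occupied else p.k2 * s
            rev = p.k_minus2 * pe
            comp = p.k3 * pe
            out[iU] += -bUS + bSU
            out[iS] += bUS - bSU - bSD + bDS - syn + rev
            out[iD] += bSD - bDS
            out[iP] += syn - rev - comp
            out[0] += -bUS + bSU - bSD + bDS + comp
            if sec_occupied:
                out[0] += comp  # the secondary-site dimer is released too
        # completed transposons (and their gained siblings) re-enter U
        out[2] += (1 + g) * total_comp
        out[0] += -ns - sec_bound_flux + E * g * total_comp
        out[1] += ns
        return out


class SpdModel(KineticModel):
    """Protein-dimerization assembly (monomeric transposase).

    Monomers fill the two ends (``U -> S -> D``); the doubly-bound state
    synapses by dimerization of the bound monomers at ``k2``.  Variant
    hooks: a cis-acting fraction of expression feeds a private per-copy
    pool whose completion propensity is solved from the single-copy
    stationary chain, and a trans-acting inhibitor scales the effective
    expression by ``1/(1 + potency)`` (inhibitor and transposase are
    co-expressed, so the suppression is copy-number independent and applies
    to cis and bulk expression alike).
    """

    species = ("T_free", "T_nsb", "U", "S", "D", "P")
    transposon_pools = (2, 3, 4, 5)

    def __init__(self, params: KineticParameterSet, ctx: CellContext):
        super().__init__(params, ctx)
        suppression = 1.0 / (1.0 + params.inhibitor_potency)
        self.bulk_expression = (
            (1.0 - params.cis_fraction) * ctx.expression_per_copy * suppression
        )
        self.r_cis = 0.0
        if params.cis_fraction > 0:
            # the private pool is also buffered by non-specific chromatin
            # binding, so only its equilibrium free fraction acts on the ends
            c_cis = ctx.count_to_molar(
                params.cis_fraction
                * ctx.expression_per_copy
                * suppression
                * self._free_fraction()
            )
            self.r_cis = self._single_copy_completion_rate(c_cis)

    def _single_copy_completion_rate(self, conc: float) -> float:
        """Stationary completion propensity of one copy at clamped monomer conc.

        Solves the four-state cycle U->S->D->P->U (binding at ``k1*c`` with
        the two-end statistical factors, synapsis ``k2``, maturation
        ``k3``) for its stationary distribution; the propensity is
        ``k3 * pi_P``.
        """
        p = self.params
        kb = p.k1 * conc
        # generator matrix over (U, S, D, P), columns sum to zero
        Q = np.array(
            [
                [-2 * kb, p.k_minus1, 0.0, p.k3],
                [2 * kb, -(p.k_minus1 + kb), 2 * p.k_minus1, 0.0],
                [0.0, kb, -(2 * p.k_minus1 + p.k2), p.k_minus2],
                [0.0, 0.0, p.k2, -(p.k_minus2 + p.k3)],
            ]
        )
        A = np.vstack([Q, np.ones(4)])
        b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        return float(p.k3 * max(pi[3], 0.0))

    def expression_units_per_copy(self) -> float:
        return self.bulk_expression

    def initial_state(self, n0: float = 1.0) -> np.ndarray:
        y = np.zeros(6)
        y[0] = self.bulk_expression * n0
        y[2] = n0
        return y

    def transposase_units(self, y) -> float:
        Tf, Tn, U, S, D, P = y
        return float(Tf + Tn + S + 2 * D + 2 * P)

    def completion_flux(self, y) -> float:
        return self.params.k3 * y[5] + self.r_cis * self.copy_number(y)

    def rhs(self, t, y):
        p = self.params
        g = self.log_gain
        Tf, Tn, U, S, D, P = y
        N = U + S + D + P
        ns = self.c0 * Tf * self.s_ns - p.k_minus0 * Tn
        bUS = 2 * self.c1 * Tf * U
        bSU = p.k_minus1 * S
        bSD = self.c1 * Tf * S
        bDS = 2 * p.k_minus1 * D
        syn = p.k2 * D
        rev = p.k_minus2 * P
        comp = p.k3 * P
        growth = g * (comp + self.r_cis * N)  # net new copies / s
        dTf = -ns - bUS + bSU - bSD + bDS + 2 * comp + self.bulk_expression * growth
        dTn = ns
        dU = -bUS + bSU + comp + growth
        dS = bUS - bSU - bSD + bDS
        dD = bSD - bDS - syn + rev
        dP = syn - rev - comp
        return np.array([dTf, dTn, dU, dS, dD, dP])


class DeoModel(KineticModel):
    """Dimerization end occlusion: active monomers, inhibitory free dimers.

    Only *free* monomers dimerize (the simplified scheme); the inactive
    dimer binds and occludes transposon ends.  A transposon end is empty,
    monomer-bound or dimer-bound; with two identical ends the unordered
    pools are ``EE, EM, ED, MM, MD, DD`` plus the synapse ``P`` (formed
    from ``MM``, the sole productive species).  Monomers and dimers both
    exchange with the constant non-specific pool at ``k0``/``k-0``.
    """

    species = (
        "M_free", "M_nsb", "D_free", "D_nsb",
        "EE", "EM", "ED", "MM", "MD", "DD", "P",
    )
    transposon_pools = (4, 5, 6, 7, 8, 9, 10)

    def __init__(self, params: KineticParameterSet, ctx: CellContext):
        super().__init__(params, ctx)
        kdim = params.deo_dimerization_k
        self.c_dim = ctx.per_pair_rate(params.k1 if kdim is None else kdim)
        self.c_dimer_end = self.c1 * params.deo_dimer_end_affinity_multiplier

    def initial_state(self, n0: float = 1.0) -> np.ndarray:
        y = np.zeros(11)
        y[0] = self.ctx.expression_per_copy * n0
        y[4] = n0
        return y

    def transposase_units(self, y) -> float:
        M, Mn, Df, Dn, EE, EM, ED, MM, MD, DD, P = y
        return float(
            M + Mn + 2 * (Df + Dn)
            + EM + 2 * ED + 2 * MM + 3 * MD + 4 * DD + 2 * P
        )

    def completion_flux(self, y) -> float:
        return self.params.k3 * y[10]

    def rhs(self, t, y):
        p = self.params
        g = self.log_gain
        E = self.ctx.expression_per_copy
        M, Mn, Df, Dn, EE, EM, ED, MM, MD, DD, P = y
        ns_m = self.c0 * M * self.s_ns - p.k_minus0 * Mn
        ns_d = self.c0 * Df * self.s_ns - p.k_minus0 * Dn
        dimz = self.c_dim * M * M  # 2M -> inactive dimer
        undim = p.k_minus1 * Df
        cm = self.c1 * M  # monomer association per empty end
        cd = self.c_dimer_end * Df  # dimer association per empty end
        km = p.k_minus1
        # transitions between transposon pools
        f_EE_EM = 2 * cm * EE
        f_EE_ED = 2 * cd * EE
        f_EM_EE = km * EM
        f_EM_MM = cm * EM
        f_EM_MD = cd * EM
        f_ED_EE = km * ED
        f_ED_MD = cm * ED
        f_ED_DD = cd * ED
        f_MM_EM = 2 * km * MM
        f_MD_EM = km * MD  # dimer off
        f_MD_ED = km * MD  # monomer off
        f_DD_ED = 2 * km * DD
        syn = p.k2 * MM
        rev = p.k_minus2 * P
        comp = p.k3 * P
        dEE = -f_EE_EM - f_EE_ED + f_EM_EE + f_ED_EE + (1 + g) * comp
        dEM = f_EE_EM - f_EM_EE - f_EM_MM - f_EM_MD + f_MM_EM + f_MD_EM
        dED = f_EE_ED - f_ED_EE - f_ED_MD - f_ED_DD + f_MD_ED + f_DD_ED
        dMM = f_EM_MM - f_MM_EM - syn + rev
        dMD = f_EM_MD + f_ED_MD - f_MD_EM - f_MD_ED
        dDD = f_ED_DD - f_DD_ED
        dP = syn - rev - comp
        mono_on = cm * (2 * EE + EM + ED)
        mono_off = km * (EM + 2 * MM + MD)
        dim_on = cd * (2 * EE + EM + ED)
        dim_off = km * (ED + MD + 2 * DD)
        dM = (
            -ns_m - 2 * dimz + 2 * undim - mono_on + mono_off
            + 2 * comp + E * g * comp
        )
        dMn = ns_m
        dDf = -ns_d + dimz - undim - dim_on + dim_off
        dDn = ns_d
        return np.array([dM, dMn, dDf, dDn, dEE, dEM, dED, dMM, dMD, dDD, dP])


_MECHANISMS = {"snec": SnecModel, "spd": SpdModel, "deo": DeoModel}


def build_model(mechanism: str, params: KineticParameterSet, ctx: CellContext) -> KineticModel:
    try:
        cls = _MECHANISMS[mechanism]
    except KeyError:
        raise KeyError(
            f"unknown mechanism {mechanism!r}; available: {sorted(_MECHANISMS)}"
        ) from None
    return cls(params, ctx)


# ---------------------------------------------------------------------------
# in vitro (test-tube) reaction: fixed substrate, no genome, no expression


def simulate_invitro_reaction(
    params: KineticParameterSet,
    substrate_M: float,
    transposase_M: float,
    times,
    *,
    preassembled: bool = False,
    binding_preequilibrated: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-15,
):
    """Integrate the naked-end-capture scheme for a test-tube reaction.

    Species are molar: free transposase dimer ``T`` and substrate pools
    ``U, S, D, P`` plus the cumulative matured product ``C``.  There is no
    genome (no non-specific sink), no expression and no copy-number
    coupling; maturation converts ``P`` into product and releases the
    dimer.  ``preassembled=True`` starts with every substrate molecule in
    the paired-ends complex (the transposase it contains is *in addition*
    to ``transposase_M``, mirroring staged assembly before a challenge).
    ``binding_preequilibrated=True`` starts from the binding equilibrium
    without synapsis (random assortment of dimers over ends), emulating a
    pre-incubation before the catalytic metal ion starts the reaction; at
    the optimal ratio of one dimer per transposon this is the
    quarter/half/quarter assortment in which only the singly-occupied half
    of the substrate can react at first.

    Returns ``(times, states)`` with states of shape (6, n): rows
    ``T, U, S, D, P, C``.
    """
    from scipy.integrate import solve_ivp

    p = params

    def rhs(t, y):
        T, U, S, D, P, C = y
        bUS = 2 * p.k1 * T * U
        bSU = p.k_minus1 * S
        bSD = p.k1 * T * S
        bDS = 2 * p.k_minus1 * D
        syn = p.k2 * S
        rev = p.k_minus2 * P
        comp = p.k3 * P
        return [
            -bUS + bSU - bSD + bDS + comp,
            -bUS + bSU,
            bUS - bSU - bSD + bDS - syn + rev,
            bSD - bDS,
            syn - rev - comp,
            comp,
        ]

    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if preassembled:
        y0 = [transposase_M, 0.0, 0.0, 0.0, substrate_M, 0.0]
    elif binding_preequilibrated:
        kd = p.specific_kd
        # free pool from conservation T = t + 2*substrate*t/(t+kd): quadratic
        b = kd + 2.0 * substrate_M - transposase_M
        t_free = 0.5 * (-b + math.sqrt(b * b + 4.0 * kd * transposase_M))
        theta = t_free / (t_free + kd)
        y0 = [
            t_free,
            (1 - theta) ** 2 * substrate_M,
            2 * theta * (1 - theta) * substrate_M,
            theta**2 * substrate_M,
            0.0,
            0.0,
        ]
    else:
        y0 = [transposase_M, substrate_M, 0.0, 0.0, 0.0, 0.0]
    t_end = float(times.max()) if times.size else 0.0
    if t_end == 0.0:
        return times, np.tile(np.asarray(y0)[:, None], (1, times.size))
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method="LSODA", rtol=rtol, atol=atol, t_eval=times
    )
    if not sol.success:  # pragma: no cover - solver diagnostics
        raise RuntimeError(f"in vitro reaction integration failed: {sol.message}")
    return sol.t, sol.y
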