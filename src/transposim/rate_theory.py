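"""Physical rate theory for transposase-DNA association and synapsis.

This module derives the kinetic constants of transpososome assembly from
diffusion physics:

* the Collins-Kimball partition of an observed bimolecular rate constant
  into a diffusion-limited and an activation-limited part,
* Berg's worm-like-chain expressions for the diffusion-limited association
  of a free protein to a specific DNA site and of a DNA-bound protein to a
  second site, and
* an empirical worm-like-chain estimate of the local molar concentration
  ``j_M`` of one DNA site in the vicinity of another on the same molecule,
  which converts the second-end capture rate constant into the
  pseudo-first-order synapsis rate ``k2 = k1' * j_M``.

All bimolecular rate constants are handled in M^-1 s^-1; the diffusion
formulas are evaluated in volume/time (um^3/s) and converted via Avogadro's
number.  Lengths are supplied in nm (persistence length, reaction radius)
and bp (site separation), diffusion coefficients in um^2/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "AVOGADRO",
    "RateTheoryInputs",
    "DerivedRates",
    "molar_rate_to_volume_rate",
    "volume_rate_to_molar_rate",
    "halflife_to_rate",
    "rate_to_halflife",
    "k1_diff_free",
    "k1_diff_bound",
    "collins_kimball_kact",
    "collins_kimball_compose",
    "local_concentration_jM",
    "k2_synapsis",
    "derive_parameter_table",
    "load_inputs",
    "preset_inputs",
]

#: Avogadro's number (mol^-1).
AVOGADRO = 6.022e23

_NM_TO_UM = 1e-3


@dataclass(frozen=True)
class RateTheoryInputs:
    """Physical inputs of the rate-theory chain.

    Parameters
    ----------
    persistence_length_a:
        DNA persistence length in nm (the worm-like-chain bending length).
    reaction_radius_R:
        Distance in nm over which the specific protein-DNA interaction
        occurs (hard-sphere collision radius of binding domain + site).
    segmental_diffusion_Ds:
        Short-range ("segmental") diffusion coefficient of a DNA site, in
        um^2/s; the translational diffusion coefficient of a free DNA
        fragment one persistence length long.
    protein_diffusion_Dp:
        Diffusion coefficient of the free protein relative to the DNA
        centre of mass, in um^2/s.
    measured_k1:
        Experimentally determined specific association rate constant, in
        M^-1 s^-1; used to extract the activation-limited part.
    site_separation_b:
        Contour separation of the two specific sites in bp (transposon
        length), used for the local-concentration estimate.
    """

    persistence_length_a: float = 50.0
    reaction_radius_R: float = 2.5
    segmental_diffusion_Ds: float = 27.0
    protein_diffusion_Dp: float = 61.0
    measured_k1: float = 3.8e8
    site_separation_b: float = 1287.0

    def __post_init__(self) -> None:
        for name in (
            "persistence_length_a",
            "reaction_radius_R",
            "segmental_diffusion_Ds",
            "protein_diffusion_Dp",
            "measured_k1",
            "site_separation_b",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.reaction_radius_R < self.persistence_length_a:
            raise ValueError(
                "reaction_radius_R must be smaller than persistence_length_a "
                "for the (R/a)^(1/3) short-segment regime to apply"
            )


@dataclass(frozen=True)
class DerivedRates:
    """Derived kinetic constants of the assembly chain (molar units)."""

    k1_diff: float  # diffusion limit, free protein -> site (M^-1 s^-1)
    k_act: float  # activation-limited part (M^-1 s^-1)
    k1_diff_prime: float  # diffusion limit, bound protein -> site (M^-1 s^-1)
    k1_prime: float  # effective second-end capture constant (M^-1 s^-1)
    local_conc_B: float  # local concentration of the partner site (M)
    k2: float  # pseudo-first-order synapsis rate (s^-1)
    k1_effective: float = field(default=math.nan)
    # k1 recomposed from k1_diff and k_act; equals the measured k1 when
    # k_act was extracted from the same k1_diff, and gives the
    # crowding-penalised first-end rate when k_act is carried over from
    # the dilute-solution chain.

    def __post_init__(self) -> None:
        if self.k1_prime > min(self.k1_diff_prime, self.k_act) * (1 + 1e-12):
            raise ValueError("k1_prime exceeds its Collins-Kimball bound")


def molar_rate_to_volume_rate(k: float) -> float:
    """Convert a bimolecular rate constant from M^-1 s^-1 to um^3 s^-1.

    This is the per-molecule-pair reaction volume swept per unit time, the
    natural unit when species are counted as molecules per cubic
    micrometer.  ``k`` must be non-negative.
    """
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    return k * 1e15 / AVOGADRO


def volume_rate_to_molar_rate(k: float) -> float:
    """Inverse of :func:`molar_rate_to_volume_rate` (um^3 s^-1 -> M^-1 s^-1)."""
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    return k * AVOGADRO / 1e15


def halflife_to_rate(t_half: float) -> float:
    """First-order rate constant (s^-1) from a half-life (s): ln2 / t_half."""
    if not t_half > 0:
        raise ValueError("half-life must be strictly positive")
    return math.log(2.0) / t_half


def rate_to_halflife(k: float) -> float:
    """Half-life (s) of a first-order process with rate constant ``k`` (s^-1)."""
    if not k > 0:
        raise ValueError("rate constant must be strictly positive")
    return math.log(2.0) / k


def _segmental_term(inputs: RateTheoryInputs) -> float:
    """D_s * a * (R/a)^(1/3) in um^3/s (lengths converted nm -> um)."""
    a = inputs.persistence_length_a * _NM_TO_UM
    R = inputs.reaction_radius_R * _NM_TO_UM
    return inputs.segmental_diffusion_Ds * a * (R / a) ** (1.0 / 3.0)


def k1_diff_free(inputs: RateTheoryInputs) -> float:
    """Diffusion-limited association rate of a free protein to a DNA site.

    Berg's worm-like-chain result ``4*pi*Dp*R + Ds*a*(R/a)^(1/3)``,
    evaluated in um^3/s and returned in M^-1 s^-1.  The first term is the
    Smoluchowski rate for the protein reaching the site, the second the
    segmental motion of the site itself.
    """
    R = inputs.reaction_radius_R * _NM_TO_UM
    vol_rate = 4.0 * math.pi * inputs.protein_diffusion_Dp * R + _segmental_term(inputs)
    return volume_rate_to_molar_rate(vol_rate)


def k1_diff_bound(inputs: RateTheoryInputs) -> float:
    """Diffusion-limited association rate of a DNA-bound protein to a second site.

    Berg's result ``1.4 * Ds * a * (R/a)^(1/3)`` in um^3/s, returned in
    M^-1 s^-1.  Only segmental DNA motion contributes because the protein
    is dragged by the chromosome.
    """
    return volume_rate_to_molar_rate(1.4 * _segmental_term(inputs))


def collins_kimball_kact(k_obs: float, k_diff: float) -> float:
    """Activation-limited rate constant from 1/k_obs = 1/k_diff + 1/k_act.

    Raises ``ValueError`` when ``k_obs >= k_diff`` (a reaction cannot be
    observed faster than its diffusion limit).
    """
    if not 0 < k_obs:
        raise ValueError("observed rate must be positive")
    if not k_obs < k_diff:
        raise ValueError(
            "observed rate >= diffusion limit: reaction faster than diffusion "
            "limit has no activation-limited decomposition"
        )
    return 1.0 / (1.0 / k_obs - 1.0 / k_diff)


def collins_kimball_compose(k_diff_prime: float, k_act: float) -> float:
    """Harmonic composition 1/k = 1/k_diff' + 1/k_act (both positive).

    ``k_act = inf`` is allowed and returns ``k_diff_prime`` (no activation
    barrier).
    """
    if not k_diff_prime > 0 or not k_act > 0:
        raise ValueError("both rate constants must be positive")
    return 1.0 / (1.0 / k_diff_prime + 1.0 / k_act)


def local_concentration_jM(a: float, b: float) -> float:
    """Local molar concentration of one DNA site near another on the same chain.

    Empirical worm-like-chain expression

    ``j_M = (4a / (1e4 b))^(3/2) * exp(-460 a^2 / (6.25 b^2)) * (1.25e5 / a^3)``

    with ``a`` the persistence length in nm and ``b`` the site separation
    in bp; the result is in molar.  The Gaussian-chain power law carries
    the large-separation behaviour while the exponential suppresses
    separations too short to loop.
    """
    if not a > 0 or not b > 0:
        raise ValueError("persistence length and site separation must be positive")
    gaussian = (4.0 * a / (1e4 * b)) ** 1.5
    stiffness = math.exp(-460.0 * a * a / (6.25 * b * b))
    scale = 1.25e5 / a**3
    return gaussian * stiffness * scale


def k2_synapsis(k1_prime: float, local_conc: float) -> float:
    """Pseudo-first-order synapsis rate: second-end capture constant times j_M."""
    if k1_prime < 0 or local_conc < 0:
        raise ValueError("rate constant and concentration must be non-negative")
    return k1_prime * local_conc


def derive_parameter_table(
    inputs: RateTheoryInputs, *, k_act: float | None = None
) -> DerivedRates:
    """Chain the full derivation from physical inputs to the synapsis rate.

    The chain is: free-protein diffusion limit -> activation-limited part
    (from the measured k1) -> bound-protein diffusion limit -> effective
    second-end constant k1' -> local concentration j_M -> k2 = k1' * j_M.

    Parameters
    ----------
    inputs:
        Physical inputs; under crowded (in vivo) diffusion coefficients the
        measured k1 can exceed the crowded diffusion limit, in which case
        the activation-limited part must be supplied via ``k_act``.
    k_act:
        Optional activation-limited rate carried over from another
        (typically dilute-solution) chain.  When given, the first-end rate
        ``k1_effective`` is recomposed from the local diffusion limit and
        this ``k_act``, giving the crowding-penalised association rate.
    """
    k1d = k1_diff_free(inputs)
    if k_act is None:
        k_act = collins_kimball_kact(inputs.measured_k1, k1d)
    k1dp = k1_diff_bound(inputs)
    k1p = collins_kimball_compose(k1dp, k_act)
    jM = local_concentration_jM(
        inputs.persistence_length_a, inputs.site_separation_b
    )
    return DerivedRates(
        k1_diff=k1d,
        k_act=k_act,
        k1_diff_prime=k1dp,
        k1_prime=k1p,
        local_conc_B=jM,
        k2=k2_synapsis(k1p, jM),
        k1_effective=collins_kimball_compose(k1d, k_act),
    )


# ---------------------------------------------------------------------------
# presets


def load_inputs(path) -> RateTheoryInputs:
    """Load :class:`RateTheoryInputs` from a YAML mapping file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    fields = {
        k: float(v)
        for k, v in raw.items()
        if k in RateTheoryInputs.__dataclass_fields__
    }
    return RateTheoryInputs(**fields)


def preset_inputs(name: str) -> RateTheoryInputs:
    """Return a shipped physical-input preset: ``in_vitro`` or ``in_vivo``."""
    from importlib import resources

    ref = resources.files("transposim.presets") / f"{name}.yaml"
    if not ref.is_file():
        raise KeyError(f"unknown rate-theory preset {name!r}; available: in_vitro, in_vivo")
    with resources.as_file(ref) as path:
        return load_inputs(path)
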