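"""Hepatocyte reaction rate laws and state derivatives.

Sixteen enzyme-level rates cover fructolysis (fructokinase, aldolase B,
triose-phosphate isomerase both directions, triokinase), lower glycolysis
and gluconeogenesis (pyruvate kinase, PEPCK), pyruvate oxidation (PDC),
lipid metabolism (fatty-acid synthesis, beta-oxidation, triglyceride
synthesis, lipolysis) and the glucose branch (glucokinase, G6Pase, FBPase,
PFK).  Each law is a product of a V_max, Hill/Michaelis-Menten saturation
factors in substrates and clamped cofactor pools, and allosteric factors
of the form ``1 - beta*X/(Ki + X)`` with ``beta`` in [0, 1] -- so every
rate is non-negative for any non-negative state.

Cofactors (ATP, ADP, ATP-Mg, GTP, NAD(H), Pi) are clamped constants read
from the :class:`~fructolyse.parameters.ParameterSet`.
"""

from __future__ import annotations

from typing import NamedTuple

from .parameters import ParameterSet

__all__ = [
    "HepaticState",
    "RateVector",
    "saturation_term",
    "inhibition_term",
    "evaluate_hepatic_rates",
    "hepatic_derivatives",
    "STOICHIOMETRY_MODES",
]

STOICHIOMETRY_MODES = ("paper-faithful", "carbon-consistent")


class HepaticState(NamedTuple):
    """Hepatocyte metabolite concentrations (uM)."""

    Fru: float
    F1P: float
    DHAP: float
    GA: float
    GA3P: float
    Pyr: float
    ACoA: float
    FA: float
    TG: float
    Glu: float
    G6P: float


class RateVector(NamedTuple):
    """Instantaneous hepatocyte reaction rates (uM/s)."""

    R_KHK: float
    R_aldB: float
    R_TPI_DHAP: float
    R_TPI_GA3P: float
    R_Tri: float
    R_PK: float
    R_PEPCK: float
    R_PDC: float
    R_FAS: float
    R_boxi: float
    R_TGS: float
    R_Lply: float
    R_GK: float
    R_G6Pase: float
    R_FBP: float
    R_PFK: float


def saturation_term(S: float, Km: float, n: float = 1.0) -> float:
    """Hill saturation ``S^n / (Km^n + S^n)``, in [0, 1].

    ``n = 1`` reduces to the Michaelis-Menten form.  Zero at ``S = 0``
    and 1/2 at ``S = Km`` for any exponent.
    """
    if S < 0:
        raise ValueError(f"negative substrate concentration: {S}")
    if Km <= 0:
        raise ValueError(f"Km must be > 0, got {Km}")
    if n < 1:
        raise ValueError(f"Hill exponent must be >= 1, got {n}")
    if S == 0.0:
        return 0.0
    if n == 1.0:
        return S / (Km + S)
    sn = S**n
    return sn / (Km**n + sn)


def inhibition_term(X: float, Ki: float, beta: float) -> float:
    """Allosteric factor ``1 - beta*X/(Ki + X)``, in [1-beta, 1]."""
    if not (0.0 <= beta <= 1.0):
        raise ValueError(f"inhibition strength beta must lie in [0,1], got {beta}")
    if X < 0:
        raise ValueError(f"negative inhibitor concentration: {X}")
    if Ki <= 0:
        raise ValueError(f"Ki must be > 0, got {Ki}")
    return 1.0 - beta * X / (Ki + X)


def evaluate_hepatic_rates(state: HepaticState, p: ParameterSet) -> RateVector:
    """Evaluate all sixteen hepatocyte rate laws at one state.

    Raises
    ------
    ValueError
        If any state component is negative.
    """
    s = HepaticState(*state)
    sat, inh = saturation_term, inhibition_term
    ATP, ADP, ATPMg, GTP = p["ATP"], p["ADP"], p["ATPMg"], p["GTP"]

    R_KHK = (
        p["V_KHK"]
        * sat(s.Fru, p["Km_KHK"], p["n_Fru"])
        * sat(ATP, p["Km_ATP"], p["n_ATP"])
    )
    R_aldB = p["V_aldB"] * sat(s.F1P, p["Km_F1P"], p["n_F1P"])
    R_TPI_DHAP = p["V_TPI_DHAP"] * sat(s.DHAP, p["Km_DHAP"], p["n_DHAP"])
    R_TPI_GA3P = p["V_TPI_GA3P"] * sat(s.GA3P, p["Km_TPIGA3P"], p["n_GA3P"])
    R_Tri = (
        p["V_Tri"]
        * sat(s.GA, p["Km_GA"], p["n_GA"])
        * sat(ATPMg, p["Km_ATPMg"], p["n_ATPMg"])
        * inh(ATP, p["Ki_ATP"], p["beta_ATP"])
        * inh(ADP, p["Ki_ADP"], p["beta_ADP"])
    )
    R_PK = (
        p["V_PK"]
        * sat(s.GA3P, p["Km_GA3P"], p["n_GA3P"])
        * sat(ADP, p["Km_ADPpk"], p["n_ADPpk"])
        * inh(s.ACoA, p["Ki_ACoA_PK"], p["beta_ACoA_PK"])
    )
    R_PEPCK = (
        p["V_PEPCK"]
        * sat(s.Pyr, p["Km_PEPCK"])
        * sat(ATP, p["Km_ATPpepck"])
        * sat(GTP, p["Km_GTP"])
    )
    R_PDC = (
        p["V_PDC"]
        * sat(s.Pyr, p["Km_Pyr"])
        * inh(s.ACoA, p["ki_CoA_pyr"], p["beta_ACoA_PDC"])
    )
    R_FAS = (
        p["V_FAS"]
        * sat(s.ACoA, p["Km_ACoA"])
        * sat(ATP, p["Km_ATPfas"])
        * inh(s.FA, p["ki_FA_inhib"], p["beta_FA"])
    )
    R_boxi = (
        p["V_boxi"]
        * sat(s.FA, p["Km_boxi"])
        * sat(ATP, p["Km_ATPboxi"])
        * inh(s.ACoA, p["ki_CoA_boxi"], p["beta_boxi"])
        * inh(s.F1P, p["ki_F1P_inhib"], p["beta_PPARa"])
    )
    R_TGS = (
        p["V_TGS"] * sat(s.FA, p["Km_FA"]) * sat(s.GA3P, p["Km_TGSGA3P"])
    )
    R_Lply = p["V_Lply"] * sat(s.TG, p["Km_TG"])
    R_GK = (
        p["V_GK"]
        * sat(s.Glu, p["Km_Glu"], p["n_Glu"])
        * sat(ATP, p["Km_ATPgk"], p["n_ATP"])
        * inh(s.G6P, p["ki_G6P"], 1.0)
    )
    R_G6Pase = p["V_G6Pase"] * sat(s.G6P, p["Km_G6Pase"])
    R_FBP = p["V_FBP"] * sat(s.GA3P, p["Km_FBP"])
    R_PFK = (
        p["V_PFK"]
        * sat(s.G6P, p["Km_PFK"])
        * sat(ATP, p["Km_ATPpfk"])
        * (1.0 - sat(ATP, p["ki_ATPfpk"]) * sat(ADP, p["ki_ADPfpk"]))
        * inh(s.GA3P, p["ki_GA3Ppfk"], p["beta_PFK"])
    )
    return RateVector(
        R_KHK, R_aldB, R_TPI_DHAP, R_TPI_GA3P, R_Tri, R_PK, R_PEPCK,
        R_PDC, R_FAS, R_boxi, R_TGS, R_Lply, R_GK, R_G6Pase, R_FBP, R_PFK,
    )


def hepatic_derivatives(
    rates: RateVector,
    transports,
    mode: str = "paper-faithful",
) -> HepaticState:
    """Assemble d/dt of the eleven hepatocyte species (uM/s).

    ``transports`` is a :class:`~fructolyse.exchange.TransportVector`
    (positive = into the hepatocyte).

    The source ODE table omits the triglyceride-synthesis, PFK and FBPase
    terms from dGA3P/dt and the lipolysis glyceraldehyde return from
    dGA/dt, even though the reaction stoichiometries imply them.  Mode
    ``"paper-faithful"`` (default) reproduces the table as printed;
    ``"carbon-consistent"`` restores the implied terms.
    """
    if mode not in STOICHIOMETRY_MODES:
        raise ValueError(f"unknown stoichiometry mode {mode!r}")
    r = rates
    dFru = transports.T_Fru - r.R_KHK
    dF1P = r.R_KHK - r.R_aldB
    dDHAP = r.R_aldB - r.R_TPI_DHAP + r.R_TPI_GA3P
    dGA = r.R_aldB - r.R_Tri
    dGA3P = r.R_TPI_DHAP - r.R_TPI_GA3P + r.R_Tri - r.R_PK + r.R_PEPCK
    if mode == "carbon-consistent":
        dGA += r.R_Lply
        dGA3P += r.R_PFK - r.R_FBP - r.R_TGS
    dPyr = transports.T_Pyr + r.R_PK - r.R_PDC - r.R_PEPCK
    # one palmitate costs eight acetyl-CoA; beta-oxidation returns eight
    dACoA = r.R_PDC - 8.0 * r.R_FAS + 8.0 * r.R_boxi
    dFA = (
        transports.T_FA + r.R_FAS - r.R_boxi - 3.0 * r.R_TGS + 3.0 * r.R_Lply
    )
    dTG = transports.T_TG + r.R_TGS - r.R_Lply
    dGlu = transports.T_Glu - r.R_GK + r.R_G6Pase
    dG6P = r.R_GK - r.R_G6Pase + r.R_FBP - r.R_PFK
    return HepaticState(
        dFru, dF1P, dDHAP, dGA, dGA3P, dPyr, dACoA, dFA, dTG, dGlu, dG6P
    )
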