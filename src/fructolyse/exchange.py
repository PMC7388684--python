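"""Cross-membrane transport, blood circulation, and whole-body closures.

Three layers of exchange connect the compartments:

* hepatic blood <-> hepatocyte transport (GLUT carriers, passive exchange,
  insulin-modulated fatty-acid uptake and the VLDL-like triglyceride
  export), in the altered Michaelis-Menten form
  ``Vmax*(S_out - S_in)/(Km + S_out + S_in)``;
* systemic <-> hepatic blood circulation at turnover rate ``R_BS``,
  volume-weighted so circulation alone conserves moles;
* hormone (insulin/glucagon) secretion-clearance dynamics and the
  periphery (muscle/adipose) consumption and release terms that close the
  systemic blood balance.

Hormones are tracked in basal-normalised dimensionless units: 1.0 is the
fasted reference level.  The hormone and periphery closures are this
package's own reconstruction (simple Hill/Michaelis-Menten shapes around a
glucose setpoint); their constants are tagged ``reconstructed`` in the
parameter file.
"""

from __future__ import annotations

from typing import NamedTuple

from .kinetics import HepaticState, inhibition_term, saturation_term
from .parameters import ParameterSet

__all__ = [
    "BloodState",
    "TransportVector",
    "PeripheryFluxes",
    "bidirectional_exchange",
    "evaluate_transports",
    "circulation_flux",
    "circulation_pair",
    "hormone_derivatives",
    "periphery_fluxes",
]


class BloodState(NamedTuple):
    """Blood-compartment state: metabolites in uM, hormones normalised."""

    Fru: float
    Glu: float
    Pyr: float
    FA: float
    TG: float
    Ins: float
    Gcg: float


class TransportVector(NamedTuple):
    """Net hepatic-blood -> hepatocyte fluxes (uM/s, positive inward)."""

    T_Fru: float
    T_Glu: float
    T_Pyr: float
    T_FA: float
    T_TG: float


class PeripheryFluxes(NamedTuple):
    USE_Glu: float
    USE_FA: float
    USE_TG: float
    UP_FA: float
    UP_TG: float


def bidirectional_exchange(
    S_out: float, S_in: float, Vmax: float, Km: float
) -> float:
    """Facilitated exchange ``Vmax*(S_out - S_in)/(Km + S_out + S_in)``.

    Antisymmetric in its two concentrations and zero at equality, so pure
    exchange never inverts a gradient.
    """
    if S_out < 0 or S_in < 0:
        raise ValueError(
            f"negative concentration in exchange: S_out={S_out}, S_in={S_in}"
        )
    if Vmax <= 0 or Km <= 0:
        raise ValueError("Vmax and Km must be > 0")
    return Vmax * (S_out - S_in) / (Km + S_out + S_in)


def evaluate_transports(
    shb: BloodState, sh: HepaticState, p: ParameterSet
) -> TransportVector:
    """All five hepatic-blood -> hepatocyte transport rates.

    Fructose rides GLUT2 and GLUT5, each as a unidirectional pump plus a
    bidirectional exchange; glucose analogously on a lumped GLUT carrier.
    Pyruvate/lactate is pure exchange.  Fatty acids add an active uptake
    term damped by hepatic-blood insulin.  Triglyceride exchanges against
    hepatocyte TG scaled down by ``TG_ref`` (liver TG is stored at far
    higher levels than blood TG) and loses the hepatic export flux.
    """
    ex = bidirectional_exchange
    T_Fru = (
        p["V_GLUT2pump"] * saturation_term(shb.Fru, p["Km_GLUT2pump"])
        + ex(shb.Fru, sh.Fru, p["V_GLUT2ex"], p["Km_GLUT2ex"])
        + p["V_GLUT5pump"] * saturation_term(shb.Fru, p["Km_GLUT5pump"])
        + ex(shb.Fru, sh.Fru, p["V_GLUT5ex"], p["Km_GLUT5ex"])
    )
    T_Glu = (
        p["V_GLUTGpump"] * saturation_term(shb.Glu, p["Km_GLUTGpump"])
        + ex(shb.Glu, sh.Glu, p["V_GLUTGex"], p["Km_GLUTGex"])
    )
    T_Pyr = ex(shb.Pyr, sh.Pyr, p["V_Pyrex"], p["Km_Pyrex"])
    T_FA = ex(shb.FA, sh.FA, p["V_FAex"], p["Km_FAex"]) + (
        p["V_active"]
        * shb.FA
        / ((p["Km_active"] + shb.FA) * (1.0 + shb.Ins / p["Insref_active"]))
    )
    tg_in = sh.TG / p["TG_ref"]
    T_TG = p["V_TGex"] * (shb.TG - tg_in) / (
        p["Km_TGex"] + shb.TG + tg_in
    ) - p["V_out"] * sh.TG / (p["Km_out"] + sh.TG)
    return TransportVector(T_Fru, T_Glu, T_Pyr, T_FA, T_TG)


def circulation_flux(C_sbc: float, C_shb: float, p: ParameterSet) -> float:
    """Hepatic-blood-side circulation term ``R_BS*(C_sbc - C_shb)/R_RL``."""
    return p["R_BS"] * (C_sbc - C_shb) / p["R_RL"]


def circulation_pair(
    C_sbc: float, C_shb: float, p: ParameterSet
) -> tuple[float, float]:
    """(SHB-side, SBC-side) circulation terms.

    The systemic-side term carries an extra ``1/R_RL`` so that
    ``V_liver * shb_term + (V_body - V_liver) * sbc_term = 0`` --
    circulation redistributes but never creates moles.
    """
    shb_term = circulation_flux(C_sbc, C_shb, p)
    sbc_term = -shb_term / p["R_RL"]
    return shb_term, sbc_term


def _insulin_drive(Glu: float, p: ParameterSet) -> float:
    """Normalised insulin secretion, equal to clearance of Ins=1 at setpoint."""
    n, sp = p["n_Ins"], p["Glu_setpoint"]
    return 2.0 * saturation_term(Glu, sp, n)


def _glucagon_drive(Glu: float, p: ParameterSet) -> float:
    n, sp = p["n_Gcg"], p["Glu_setpoint"]
    return 2.0 * (1.0 - saturation_term(Glu, sp, n))


def hormone_derivatives(
    sbc: BloodState, shb: BloodState, p: ParameterSet
) -> tuple[float, float, float, float]:
    """d/dt of (Ins_SHB, Gcg_SHB, Ins_SBC, Gcg_SBC).

    Systemic insulin is secreted along a rising Hill function of systemic
    glucose and cleared first-order; glucagon mirrors it with a falling
    Hill function.  Secretion is normalised so that glucose at the
    setpoint with both hormones at 1.0 is an exact fixed point.  The
    hepatic-blood hormones simply ride the circulation.
    """
    circ_ins_shb, circ_ins_sbc = circulation_pair(sbc.Ins, shb.Ins, p)
    circ_gcg_shb, circ_gcg_sbc = circulation_pair(sbc.Gcg, shb.Gcg, p)
    k_i, k_g = p["k_Ins_clear"], p["k_Gcg_clear"]
    dIns_sbc = k_i * (_insulin_drive(sbc.Glu, p) - sbc.Ins) + circ_ins_sbc
    dGcg_sbc = k_g * (_glucagon_drive(sbc.Glu, p) - sbc.Gcg) + circ_gcg_sbc
    return circ_ins_shb, circ_gcg_shb, dIns_sbc, dGcg_sbc


def periphery_fluxes(sbc: BloodState, p: ParameterSet) -> PeripheryFluxes:
    """Rest-of-body consumption (USE) and adipose release (UP) fluxes.

    USE terms are Michaelis-Menten drains on the systemic species, with
    glucose uptake stimulated by insulin (this is what blunts the blood
    glucose peaks above the setpoint).  UP terms model adipose export of
    fatty acids and triglyceride built from circulating glucose, so they
    are gated by systemic glucose availability and suppressed by insulin;
    both carbons leave the glucose pool, matching the systemic balance
    d(Glu)/dt = Meal + C - USE_Glu - UP_FA - UP_TG.
    """
    ins_boost = 1.0 + p["A_Ins_Glu"] * sbc.Ins / (p["K_Ins_Glu"] + sbc.Ins)
    USE_Glu = p["V_USE_Glu"] * saturation_term(sbc.Glu, p["Km_USE_Glu"]) * ins_boost
    USE_FA = p["V_USE_FA"] * saturation_term(sbc.FA, p["Km_USE_FA"])
    USE_TG = p["V_USE_TG"] * saturation_term(sbc.TG, p["Km_USE_TG"])
    glu_gate = saturation_term(sbc.Glu, p["Km_UP_Glu"])
    UP_FA = (
        p["V_UP_FA"] * glu_gate * inhibition_term(sbc.Ins, p["Ki_UP_FA"], p["beta_UP_FA"])
    )
    UP_TG = (
        p["V_UP_TG"] * glu_gate * inhibition_term(sbc.Ins, p["Ki_UP_TG"], p["beta_UP_TG"])
    )
    return PeripheryFluxes(USE_Glu, USE_FA, USE_TG, UP_FA, UP_TG)
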