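"""Independent symbolic transcription of the sixteen hepatocyte rate laws.

Each formula is written straight from its published table row as a sympy
expression, with no code shared with the package implementation, and
lambdified for numeric comparison.  Serves as the oracle for the
rate-law equivalence checks.
"""

import sympy as sp

# state symbols
Fru, F1P, DHAP, GA, GA3P, Pyr, ACoA, FA, TG, Glu, G6P = sp.symbols(
    "Fru F1P DHAP GA GA3P Pyr ACoA FA TG Glu G6P", nonnegative=True
)
STATE_SYMS = (Fru, F1P, DHAP, GA, GA3P, Pyr, ACoA, FA, TG, Glu, G6P)

_PARAM_NAMES = [
    "V_KHK", "Km_KHK", "n_Fru", "Km_ATP", "n_ATP",
    "V_aldB", "Km_F1P", "n_F1P",
    "V_TPI_DHAP", "Km_DHAP", "n_DHAP", "V_TPI_GA3P", "Km_TPIGA3P", "n_GA3P",
    "V_Tri", "Km_GA", "n_GA", "Km_ATPMg", "n_ATPMg",
    "beta_ATP", "Ki_ATP", "beta_ADP", "Ki_ADP",
    "V_PK", "Km_GA3P", "Km_ADPpk", "n_ADPpk", "beta_ACoA_PK", "Ki_ACoA_PK",
    "V_PEPCK", "Km_PEPCK", "Km_ATPpepck", "Km_GTP",
    "V_PDC", "Km_Pyr", "beta_ACoA_PDC", "ki_CoA_pyr",
    "V_FAS", "Km_ACoA", "Km_ATPfas", "beta_FA", "ki_FA_inhib",
    "V_boxi", "Km_boxi", "Km_ATPboxi", "beta_boxi", "ki_CoA_boxi",
    "beta_PPARa", "ki_F1P_inhib",
    "V_TGS", "Km_FA", "Km_TGSGA3P",
    "V_Lply", "Km_TG",
    "V_GK", "Km_Glu", "n_Glu", "Km_ATPgk", "ki_G6P",
    "V_G6Pase", "Km_G6Pase", "V_FBP", "Km_FBP",
    "V_PFK", "Km_PFK", "Km_ATPpfk", "ki_ATPfpk", "ki_ADPfpk",
    "beta_PFK", "ki_GA3Ppfk",
    "ATP", "ADP", "ATPMg", "GTP",
]
P = {name: sp.Symbol(name, positive=True) for name in _PARAM_NAMES}
g = P.__getitem__

ORACLE_EXPRESSIONS = {
    "R_KHK": g("V_KHK")
    * Fru ** g("n_Fru") / (g("Km_KHK") ** g("n_Fru") + Fru ** g("n_Fru"))
    * g("ATP") ** g("n_ATP")
    / (g("Km_ATP") ** g("n_ATP") + g("ATP") ** g("n_ATP")),
    "R_aldB": g("V_aldB")
    * F1P ** g("n_F1P") / (g("Km_F1P") ** g("n_F1P") + F1P ** g("n_F1P")),
    "R_TPI_DHAP": g("V_TPI_DHAP")
    * DHAP ** g("n_DHAP") / (g("Km_DHAP") ** g("n_DHAP") + DHAP ** g("n_DHAP")),
    "R_TPI_GA3P": g("V_TPI_GA3P")
    * GA3P ** g("n_GA3P")
    / (g("Km_TPIGA3P") ** g("n_GA3P") + GA3P ** g("n_GA3P")),
    "R_Tri": g("V_Tri")
    * GA ** g("n_GA") / (g("Km_GA") ** g("n_GA") + GA ** g("n_GA"))
    * g("ATPMg") ** g("n_ATPMg")
    / (g("Km_ATPMg") ** g("n_ATPMg") + g("ATPMg") ** g("n_ATPMg"))
    * (1 - g("beta_ATP") * g("ATP") / (g("Ki_ATP") + g("ATP")))
    * (1 - g("beta_ADP") * g("ADP") / (g("Ki_ADP") + g("ADP"))),
    "R_PK": g("V_PK")
    * GA3P ** g("n_GA3P") / (g("Km_GA3P") ** g("n_GA3P") + GA3P ** g("n_GA3P"))
    * g("ADP") ** g("n_ADPpk")
    / (g("Km_ADPpk") ** g("n_ADPpk") + g("ADP") ** g("n_ADPpk"))
    * (1 - g("beta_ACoA_PK") * ACoA / (g("Ki_ACoA_PK") + ACoA)),
    "R_PEPCK": g("V_PEPCK")
    * Pyr / (g("Km_PEPCK") + Pyr)
    * g("ATP") / (g("Km_ATPpepck") + g("ATP"))
    * g("GTP") / (g("Km_GTP") + g("GTP")),
    "R_PDC": g("V_PDC")
    * Pyr / (g("Km_Pyr") + Pyr)
    * (1 - g("beta_ACoA_PDC") * ACoA / (ACoA + g("ki_CoA_pyr"))),
    "R_FAS": g("V_FAS")
    * ACoA / (g("Km_ACoA") + ACoA)
    * g("ATP") / (g("Km_ATPfas") + g("ATP"))
    * (1 - g("beta_FA") * FA / (FA + g("ki_FA_inhib"))),
    "R_boxi": g("V_boxi")
    * FA / (g("Km_boxi") + FA)
    * g("ATP") / (g("Km_ATPboxi") + g("ATP"))
    * (1 - g("beta_boxi") * ACoA / (ACoA + g("ki_CoA_boxi")))
    * (1 - g("beta_PPARa") * F1P / (F1P + g("ki_F1P_inhib"))),
    "R_TGS": g("V_TGS")
    * FA / (g("Km_FA") + FA)
    * GA3P / (g("Km_TGSGA3P") + GA3P),
    "R_Lply": g("V_Lply") * TG / (g("Km_TG") + TG),
    "R_GK": g("V_GK")
    * Glu ** g("n_Glu") / (g("Km_Glu") ** g("n_Glu") + Glu ** g("n_Glu"))
    * g("ATP") ** g("n_ATP")
    / (g("Km_ATPgk") ** g("n_ATP") + g("ATP") ** g("n_ATP"))
    * (1 - G6P / (G6P + g("ki_G6P"))),
    "R_G6Pase": g("V_G6Pase") * G6P / (g("Km_G6Pase") + G6P),
    "R_FBP": g("V_FBP") * GA3P / (g("Km_FBP") + GA3P),
    "R_PFK": g("V_PFK")
    * G6P / (g("Km_PFK") + G6P)
    * g("ATP") / (g("Km_ATPpfk") + g("ATP"))
    * (
        1
        - g("ATP") / (g("ATP") + g("ki_ATPfpk"))
        * g("ADP") / (g("ADP") + g("ki_ADPfpk"))
    )
    * (1 - g("beta_PFK") * GA3P / (GA3P + g("ki_GA3Ppfk"))),
}

_ARGS = list(STATE_SYMS) + [P[n] for n in _PARAM_NAMES]
_LAMBDIFIED = {
    name: sp.lambdify(_ARGS, expr, modules="math")
    for name, expr in ORACLE_EXPRESSIONS.items()
}


def oracle_rates(state_values, params):
    """Evaluate all sixteen oracle expressions.

    state_values: sequence of the 11 hepatocyte concentrations;
    params: mapping-like object with ``[name]`` access (a ParameterSet).
    """
    pvals = [params[n] for n in _PARAM_NAMES]
    args = list(state_values) + pvals
    return {name: f(*args) for name, f in _LAMBDIFIED.items()}
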