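"""Synthetic study generator: a toy redox metabolic network plus synthetic
transcriptomic P/A calls and metabolomic intensity tables with planted
signal, so every pipeline stage is testable end to end without downloads.

The toy network is a deliberately designed test harness, not a claim of
biological realism.  It contains a glycolysis-like chain, a lumped TCA
step, oxidative phosphorylation with NAD/FAD/Q10 cofactor pairs, a
reactive-oxygen-species (ROS) branch built around superoxide dismutase
(SPODM) isoforms in five compartments, the ascorbate (Vitamin C) /
glutathione recharge cycle, xanthine oxidation to urate, and a urate
reabsorption exchange whose loss is the simulated knockout.  All internal
reactions are elementally and charge balanced; the ATP demand reaction is
the flux objective.

The simulated knockout has three coordinated facets, mirroring a renal
urate-transporter loss: the reabsorption exchange is blocked, the
transporter gene goes absent in KO expression calls, and ROS-handling
genes (absent at baseline in WT) are induced in KO — so the context-
specific KO model acquires a redox-cofactor-dominated reaction set that
the analysis stack should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gimme import ExpressionCalls
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToyNetworkSpec",
    "SimulationConfig",
    "build_redox_toy_model",
    "simulate_expression",
    "simulate_metabolomics",
    "plant_knockout",
    "random_network",
    "MODULE_GENES",
    "KNOCKOUT_EXCHANGE",
    "DEFAULT_FOLD_CHANGES",
    "METABOLITE_EXCHANGE_MAP",
]

# base-name -> (elemental formula, charge); charged species at pH 7
_FORMULAS: dict[str, tuple[str, int]] = {
    "glc__D": ("C6H12O6", 0),
    "g6p": ("C6H11O9P", -2),
    "fdp": ("C6H10O12P2", -4),
    "pyr": ("C3H3O3", -1),
    "lac__L": ("C3H5O3", -1),
    "lac__D": ("C3H5O3", -1),
    "atp": ("C10H12N5O13P3", -4),
    "adp": ("C10H12N5O10P2", -3),
    "pi": ("HO4P", -2),
    "nad": ("C21H26N7O14P2", -1),
    "nadh": ("C21H27N7O14P2", -2),
    "nadp": ("C21H25N7O17P3", -3),
    "nadph": ("C21H26N7O17P3", -4),
    "fad": ("C27H31N9O15P2", -2),
    "fadh2": ("C27H33N9O15P2", -2),
    "q10": ("C59H90O4", 0),
    "q10h2": ("C59H92O4", 0),
    "o2": ("O2", 0),
    "o2s": ("O2", -1),
    "h2o2": ("H2O2", 0),
    "h2o": ("H2O", 0),
    "h": ("H", 1),
    "co2": ("CO2", 0),
    "hco3": ("CHO3", -1),
    "na1": ("Na", 1),
    "k": ("K", 1),
    "fe2": ("Fe", 2),
    "mg2": ("Mg", 2),
    "ascb__L": ("C6H7O6", -1),
    "dhdascb": ("C6H6O6", 0),
    "gthrd": ("C10H16N3O6S", -1),
    "gthox": ("C20H30N6O12S2", -2),
    "xan": ("C5H4N4O2", 0),
    "urate": ("C5H4N4O3", 0),
    "alltn": ("C4H6N4O3", 0),
    "trdox": ("C9H13N3O5S2", 0),
    "trdrd": ("C9H15N3O5S2", 0),
    "lgt__S": ("C13H20N3O8S", -1),
}

_NAMES = {
    "o2s": "superoxide anion",
    "h2o2": "hydrogen peroxide",
    "ascb__L": "L-ascorbate (Vitamin C)",
    "dhdascb": "dehydroascorbate",
    "gthrd": "reduced glutathione",
    "gthox": "oxidized glutathione",
    "q10": "ubiquinone-10",
    "q10h2": "ubiquinol-10",
    "urate": "urate",
    "xan": "xanthine",
    "alltn": "allantoin",
    "trdox": "thioredoxin (oxidized)",
    "trdrd": "thioredoxin (reduced)",
}

#: the urate reabsorption exchange blocked by the simulated knockout
KNOCKOUT_EXCHANGE = "EX_urate_e"

#: genes of the ROS/redox-response program (absent at baseline in WT,
#: induced in the knockout)
MODULE_GENES = (
    "g_sod1", "g_sod2", "g_sod3", "g_sodn", "g_sodx", "g_cat", "g_prdx1",
    "g_ascox", "g_dhar", "g_gsto", "g_gpx1", "g_gsr", "g_nox4", "g_thd1",
    "g_fadr", "g_amox", "g_txnrd", "g_aifm", "g_xdh", "g_xdh2",
)

#: planted KO/WT fold changes of the measured plasma metabolites:
#: six elevated at 2.0, two depleted at 0.5, the rest unchanged
DEFAULT_FOLD_CHANGES: dict[str, float] = {
    "urate": 2.0,
    "alltn": 2.0,
    "h2o2": 2.0,
    "lac__L": 2.0,
    "gthrd": 2.0,
    "co2": 2.0,
    "glc__D": 0.5,
    "ascb__L": 0.5,
    "xan": 1.0,
}

#: measured metabolite base name -> model exchange reaction id
METABOLITE_EXCHANGE_MAP: dict[str, str] = {
    base: f"EX_{base}_e" for base in DEFAULT_FOLD_CHANGES
}


@dataclass
class ToyNetworkSpec:
    """Module toggles for the toy redox network."""

    ros_branch: bool = True  # SPODM isoforms, Vitamin C/glutathione cycle, NOX, ...
    glyoxalase_fixtures: bool = False  # adds the glyoxalase (GLYOX) reaction set
    objective_id: str = "ATPM"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic omics tables."""

    seed: int = 0
    expression_replicates: int = 3
    metabolomics_replicates: int = 6  # per condition, balanced over 2 batches
    dropout_rate: float = 0.02  # spurious absent-call rate for expressed genes
    absent_call_rate: float = 0.9  # per-replicate absent-call rate, planted genes
    planted_absent: dict = field(
        default_factory=lambda: {"WT": set(MODULE_GENES), "KO": {"g_urat1"}}
    )
    fold_changes: dict = field(default_factory=lambda: dict(DEFAULT_FOLD_CHANGES))
    sigma_log: float = 0.25  # log-intensity noise SD
    sigma_batch: float = 0.15  # SD of the random per-batch offset

    def __post_init__(self) -> None:
        for rate in (self.dropout_rate, self.absent_call_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def _met(base: str, comp: str) -> Metabolite:
    formula, charge = _FORMULAS[base]
    return Metabolite(
        id=f"{base}_{comp}",
        name=_NAMES.get(base, base),
        compartment=comp,
        formula=formula,
        charge=charge,
    )


def build_redox_toy_model(spec: ToyNetworkSpec | None = None) -> MetabolicModel:
    """Deterministically construct the toy redox network.

    The eight published ROS-detoxification / Vitamin C reactions (SPODM in
    five compartments, ascorbate oxidation ASCBOX_1, dehydroascorbate
    reductase DASCBR_1, glutathione-driven DHAOX_c) are hard-coded with
    exact stoichiometry.  ATP demand (ATPM) attains a positive optimum.
    """
    spec = spec or ToyNetworkSpec()

    mets: list[Metabolite] = []
    seen: set[str] = set()

    def M(base: str, comp: str) -> str:
        mid = f"{base}_{comp}"
        if mid not in seen:
            mets.append(_met(base, comp))
            seen.add(mid)
        return mid

    rxns: list[Reaction] = []

    def R(rid, stoich, lb, ub, gpr="", subsystem="", name=""):
        rxns.append(Reaction(rid, stoich, lb, ub, gpr, subsystem, name))

    def EX(base, lb=-1000.0, ub=1000.0):
        mid = M(base, "e")
        R(f"EX_{base}_e", {mid: -1.0}, lb, ub, "", "Exchange",
          name=f"{base} exchange")

    # ----- boundary -------------------------------------------------------
    EX("glc__D")
    EX("o2")
    EX("h2o")
    EX("h")
    EX("pi")
    EX("hco3")
    EX("co2")
    EX("na1")
    EX("k")
    EX("fe2")
    EX("mg2")
    EX("lac__L")
    EX("urate")          # the Urat1-like reabsorption exchange
    EX("xan")
    EX("alltn")
    EX("h2o2")
    EX("o2s", lb=0.0)  # superoxide can be shed, never taken up
    EX("ascb__L")
    EX("gthrd")

    # ----- plasma-membrane transport -------------------------------------
    R("GLCt1", {M("glc__D", "e"): -1, M("glc__D", "c"): 1}, 0, 1000,
      "g_glut1", "Transport")
    R("O2t", {M("o2", "e"): -1, M("o2", "c"): 1}, -1000, 1000, "", "Transport")
    R("H2Ot", {M("h2o", "e"): -1, M("h2o", "c"): 1}, -1000, 1000, "", "Transport")
    R("Ht", {M("h", "e"): -1, M("h", "c"): 1}, -1000, 1000, "", "Transport")
    R("PIt", {M("pi", "e"): -1, M("pi", "c"): 1}, -1000, 1000,
      "g_slc20", "Transport")
    R("CO2t", {M("co2", "c"): -1, M("co2", "e"): 1}, -1000, 1000, "", "Transport")
    R("HCO3t", {M("hco3", "c"): -1, M("hco3", "e"): 1}, -1000, 1000,
      "g_slc4", "Transport")
    R("NAt", {M("na1", "e"): -1, M("na1", "c"): 1}, -1000, 1000,
      "g_scn1", "Transport")
    R("Kt", {M("k", "e"): -1, M("k", "c"): 1}, -1000, 1000, "g_kcn1", "Transport")
    R("FE2t", {M("fe2", "e"): -1, M("fe2", "c"): 1}, -1000, 1000,
      "g_slc11", "Transport")
    R("MG2t", {M("mg2", "e"): -1, M("mg2", "c"): 1}, -1000, 1000, "", "Transport")
    R("LACt", {M("lac__L", "c"): -1, M("lac__L", "e"): 1}, 0, 1000,
      "g_mct1", "Transport")
    R("H2O2te", {M("h2o2", "c"): -1, M("h2o2", "e"): 1}, 0, 1000, "", "Transport")
    R("O2Ste", {M("o2s", "c"): -1, M("o2s", "e"): 1}, 0, 1000, "", "Transport")

    # ----- glycolysis-like chain -----------------------------------------
    R("GLYC1", {M("glc__D", "c"): -1, M("atp", "c"): -1,
                M("g6p", "c"): 1, M("adp", "c"): 1, M("h", "c"): 1},
      0, 1000, "g_hk1 or g_hk2", "Glycolysis", name="hexokinase")
    R("GLYC2", {M("g6p", "c"): -1, M("atp", "c"): -1,
                M("fdp", "c"): 1, M("adp", "c"): 1, M("h", "c"): 1},
      0, 1000, "g_pfk", "Glycolysis", name="phosphofructokinase (lumped)")
    R("GLYC3", {M("fdp", "c"): -1, M("nad", "c"): -2, M("adp", "c"): -4,
                M("pi", "c"): -2, M("pyr", "c"): 2, M("nadh", "c"): 2,
                M("atp", "c"): 4, M("h2o", "c"): 2},
      0, 1000, "g_gapdh and g_pgk and g_pyk", "Glycolysis",
      name="lower glycolysis (lumped)")
    R("LDH", {M("pyr", "c"): -1, M("nadh", "c"): -1, M("h", "c"): -1,
              M("lac__L", "c"): 1, M("nad", "c"): 1},
      -1000, 1000, "g_ldha", "Glycolysis", name="lactate dehydrogenase")

    # ----- mitochondrial core --------------------------------------------
    R("PYRtm", {M("pyr", "c"): -1, M("h", "c"): -1,
                M("pyr", "m"): 1, M("h", "m"): 1},
      0, 1000, "g_mpc1", "Transport")
    R("PYRDH", {M("pyr", "m"): -1, M("nad", "m"): -4, M("fad", "m"): -1,
                M("h2o", "m"): -3, M("co2", "m"): 3, M("nadh", "m"): 4,
                M("fadh2", "m"): 1, M("h", "m"): 3},
      0, 1000, "g_pdha and g_cs", "Citric acid cycle",
      name="pyruvate oxidation (lumped TCA)")
    R("CI", {M("nadh", "m"): -1, M("h", "m"): -1, M("q10", "m"): -1,
             M("nad", "m"): 1, M("q10h2", "m"): 1},
      0, 1000, "g_nd1", "Oxidative phosphorylation", name="complex I (lumped)")
    R("CII", {M("fadh2", "m"): -1, M("q10", "m"): -1,
              M("fad", "m"): 1, M("q10h2", "m"): 1},
      0, 1000, "g_sdha", "Oxidative phosphorylation", name="complex II")
    R("OXPHOS", {M("q10h2", "m"): -2, M("o2", "m"): -1, M("adp", "m"): -6,
                 M("pi", "m"): -6, M("h", "m"): -6, M("q10", "m"): 2,
                 M("atp", "m"): 6, M("h2o", "m"): 8},
      0, 1000, "g_atp5 and g_cox4", "Oxidative phosphorylation",
      name="complexes III-V (lumped)")
    R("ATPtm", {M("adp", "c"): -1, M("atp", "m"): -1,
                M("atp", "c"): 1, M("adp", "m"): 1},
      0, 1000, "g_ant1", "Transport", name="adenine nucleotide translocase")
    R("PItm", {M("pi", "c"): -1, M("h", "c"): -1,
               M("pi", "m"): 1, M("h", "m"): 1},
      0, 1000, "", "Transport")
    R("NADHS", {M("nadh", "c"): -1, M("nad", "m"): -1,
                M("nad", "c"): 1, M("nadh", "m"): 1},
      0, 1000, "", "Redox cofactor metabolism",
      name="malate-aspartate shuttle (lumped)")
    R("Htm", {M("h", "c"): -1, M("h", "m"): 1}, -1000, 1000, "", "Transport")
    R("O2tm", {M("o2", "c"): -1, M("o2", "m"): 1}, -1000, 1000, "", "Transport")
    R("CO2tm", {M("co2", "m"): -1, M("co2", "c"): 1}, 0, 1000, "", "Transport")
    R("H2Otm", {M("h2o", "c"): -1, M("h2o", "m"): 1}, -1000, 1000, "", "Transport")
    R("H2O2tm", {M("h2o2", "m"): -1, M("h2o2", "c"): 1}, -1000, 1000,
      "", "Transport")

    # ----- housekeeping ---------------------------------------------------
    R("CA", {M("co2", "c"): -1, M("h2o", "c"): -1,
             M("h", "c"): 1, M("hco3", "c"): 1},
      -1000, 1000, "g_ca2", "Bicarbonate metabolism", name="carbonic anhydrase")
    R("NADK", {M("atp", "c"): -1, M("nad", "c"): -1,
               M("adp", "c"): 1, M("nadp", "c"): 1, M("h", "c"): 1},
      0, 1000, "g_nadk", "Redox cofactor metabolism", name="NAD kinase")
    R("NNTm", {M("nadh", "m"): -1, M("nadp", "m"): -1,
               M("nad", "m"): 1, M("nadph", "m"): 1},
      0, 1000, "", "Redox cofactor metabolism",
      name="mitochondrial transhydrogenase")
    R("ATPM", {M("atp", "c"): -1, M("h2o", "c"): -1,
               M("adp", "c"): 1, M("pi", "c"): 1, M("h", "c"): 1},
      0, 1000, "", "Energy demand", name="ATP demand")

    # ----- urate handling (the knocked-out reabsorption route) ------------
    R("URATEt", {M("urate", "e"): -1, M("urate", "c"): 1}, -1000, 1000,
      "g_urat1", "Purine metabolism", name="urate reabsorption transporter")
    R("XANt", {M("xan", "e"): -1, M("xan", "c"): 1}, 0, 1000,
      "g_xant", "Purine metabolism")
    R("URIC", {M("urate", "c"): -1, M("o2", "c"): -1, M("h2o", "c"): -2,
               M("alltn", "c"): 1, M("co2", "c"): 1, M("h2o2", "c"): 1},
      0, 1000, "g_uox", "Purine metabolism", name="urate oxidase")
    R("ALLTNt", {M("alltn", "c"): -1, M("alltn", "e"): 1}, 0, 1000,
      "", "Purine metabolism")

    # ----- Vitamin C plumbing (constitutive part) -------------------------
    R("ASCBt", {M("ascb__L", "e"): -1, M("ascb__L", "c"): 1}, 0, 1000,
      "g_svct1", "Vitamin C metabolism", name="ascorbate importer")
    R("ASCBtm", {M("ascb__L", "c"): -1, M("ascb__L", "m"): 1}, 0, 1000,
      "", "Vitamin C metabolism")
    R("GTHRDt", {M("gthrd", "e"): -1, M("gthrd", "c"): 1}, -1000, 1000,
      "g_ggt", "Glutathione metabolism")
    R("GTHtm", {M("gthrd", "c"): -1, M("gthrd", "m"): 1}, 0, 1000,
      "", "Glutathione metabolism")

    if spec.ros_branch:
        # ----- ROS detoxification: the published SPODM isoforms ----------
        for rid, comp, gene in (
            ("SPODM", "c", "g_sod1"), ("SPODMe", "e", "g_sod3"),
            ("SPODMm", "m", "g_sod2"), ("SPODMn", "n", "g_sodn"),
            ("SPODMx", "x", "g_sodx"),
        ):
            R(rid, {M("h", comp): -2, M("o2s", comp): -2,
                    M("o2", comp): 1, M("h2o2", comp): 1},
              0, 1000, gene, "ROS detoxification", name="superoxide dismutase")
        R("CATx", {M("h2o2", "x"): -2, M("h2o", "x"): 2, M("o2", "x"): 1},
          0, 1000, "g_cat", "ROS detoxification", name="catalase")
        R("PRDX", {M("h2o2", "c"): -1, M("trdrd", "c"): -1,
                   M("h2o", "c"): 2, M("trdox", "c"): 1},
          0, 1000, "g_prdx1", "ROS detoxification", name="peroxiredoxin")

        # ----- Vitamin C cycle (published stoichiometries) ----------------
        R("ASCBOX_1", {M("h", "c"): -3, M("ascb__L", "c"): -1,
                       M("o2s", "c"): -2, M("h2o2", "c"): 2,
                       M("dhdascb", "c"): 1},
          0, 1000, "g_ascox", "Vitamin C metabolism",
          name="ascorbate oxidation by superoxide")
        R("DASCBR_1", {M("nadph", "c"): -1, M("dhdascb", "c"): -1,
                       M("nadp", "c"): 1, M("ascb__L", "c"): 1},
          0, 1000, "g_dhar", "Vitamin C metabolism",
          name="dehydroascorbate reductase (NADPH)")
        R("DHAOX_c", {M("dhdascb", "c"): -1, M("gthrd", "c"): -2,
                      M("h", "c"): 1, M("ascb__L", "c"): 1, M("gthox", "c"): 1},
          0, 1000, "g_gsto", "Vitamin C metabolism",
          name="dehydroascorbate reduction by glutathione")

        # ----- glutathione recharge ---------------------------------------
        R("GTHP", {M("gthrd", "c"): -2, M("h2o2", "c"): -1,
                   M("gthox", "c"): 1, M("h2o", "c"): 2},
          0, 1000, "g_gpx1", "Glutathione metabolism",
          name="glutathione peroxidase")
        R("GTHOr", {M("gthox", "c"): -1, M("h", "c"): -1, M("nadph", "c"): -1,
                    M("gthrd", "c"): 2, M("nadp", "c"): 1},
          0, 1000, "g_gsr", "Glutathione metabolism",
          name="glutathione reductase")

        # ----- redox cofactor maintenance ---------------------------------
        R("NOX", {M("nadph", "c"): -1, M("o2", "c"): -2,
                  M("nadp", "c"): 1, M("o2s", "c"): 2, M("h", "c"): 1},
          0, 1000, "g_nox4", "Redox cofactor metabolism", name="NADPH oxidase")
        R("THD", {M("nadh", "c"): -1, M("nadp", "c"): -1,
                  M("nad", "c"): 1, M("nadph", "c"): 1},
          0, 1000, "g_thd1", "Redox cofactor metabolism",
          name="cytosolic transhydrogenase")
        R("FADR", {M("fad", "c"): -1, M("nadh", "c"): -1, M("h", "c"): -1,
                   M("fadh2", "c"): 1, M("nad", "c"): 1},
          0, 1000, "g_fadr", "Redox cofactor metabolism", name="FAD reductase")
        R("AMOX", {M("fadh2", "c"): -1, M("o2", "c"): -1,
                   M("fad", "c"): 1, M("h2o2", "c"): 1},
          0, 1000, "g_amox", "Redox cofactor metabolism",
          name="flavin-dependent oxidase")
        R("TRDR", {M("h", "c"): -1, M("nadph", "c"): -1, M("trdox", "c"): -1,
                   M("nadp", "c"): 1, M("trdrd", "c"): 1},
          0, 1000, "g_txnrd", "Redox cofactor metabolism",
          name="thioredoxin reductase")
        R("CIIIL", {M("q10h2", "m"): -1, M("o2", "m"): -2,
                    M("q10", "m"): 1, M("o2s", "m"): 2, M("h", "m"): 2},
          0, 1000, "g_aifm", "Oxidative phosphorylation",
          name="complex III electron leak")

        # ----- xanthine oxidation to urate --------------------------------
        R("XAO", {M("xan", "c"): -1, M("o2", "c"): -2, M("h2o", "c"): -1,
                  M("urate", "c"): 1, M("o2s", "c"): 2, M("h", "c"): 2},
          0, 1000, "g_xdh", "Purine metabolism",
          name="xanthine oxidase (superoxide-producing)")
        R("XDH", {M("xan", "c"): -1, M("h2o", "c"): -1, M("nad", "c"): -1,
                  M("urate", "c"): 1, M("nadh", "c"): 1, M("h", "c"): 1},
          0, 1000, "g_xdh2", "Purine metabolism",
          name="xanthine dehydrogenase")

    if spec.glyoxalase_fixtures:
        # glyoxalase route: lactoylglutathione -> glutathione + D-lactate
        EX("lgt__S")
        EX("lac__D")
        R("LGTt", {M("lgt__S", "e"): -1, M("lgt__S", "c"): 1}, 0, 1000,
          "", "Pyruvate metabolism")
        R("GLYOX", {M("h2o", "c"): -1, M("lgt__S", "c"): -1, M("h", "c"): 1,
                    M("gthrd", "c"): 1, M("lac__D", "c"): 1},
          0, 1000, "g_hagh", "Pyruvate metabolism", name="hydroxyacylglutathione hydrolase")
        R("D_LACt", {M("lac__D", "c"): -1, M("lac__D", "e"): 1}, 0, 1000,
          "", "Transport")

    return MetabolicModel(mets, rxns, objective_id=spec.objective_id,
                          id="redox_toy")


# ---------------------------------------------------------------------------
# synthetic omics
# ---------------------------------------------------------------------------


def simulate_expression(
    model: MetabolicModel, config: SimulationConfig, condition: str
) -> ExpressionCalls:
    """Per-replicate P/A calls for one condition.

    Genes planted absent for *condition* are called absent with probability
    ``absent_call_rate`` per replicate; all other model genes are called
    present with probability ``1 − dropout_rate``.  Seeded and
    condition-keyed, so WT and KO tables from one config are independent
    but reproducible.
    """
    planted = set(config.planted_absent.get(condition, set()))
    genes = sorted(model.genes)
    missing = planted - set(genes)
    if missing:
        raise ValueError(f"planted absent genes not in model: {sorted(missing)}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1 if condition == "KO" else 0])
    )
    n_rep = config.expression_replicates
    calls = np.empty((len(genes), n_rep), dtype=bool)
    for i, gene in enumerate(genes):
        if gene in planted:
            calls[i] = rng.random(n_rep) >= config.absent_call_rate
        else:
            calls[i] = rng.random(n_rep) >= config.dropout_rate
    frame = pd.DataFrame(
        calls, index=genes, columns=[f"{condition}_rep{j+1}" for j in range(n_rep)]
    )
    return ExpressionCalls(calls=frame, condition=condition)


def simulate_metabolomics(
    model: MetabolicModel, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Log-normally noisy plasma intensities with planted fold changes.

    Returns ``(intensities, design, truth)``: a metabolite × sample table
    of positive intensities, the sample design (condition + batch, balanced)
    and the planted truth table (fold change and direction per metabolite).

    The generative model per metabolite and sample is
    ``log I = baseline + 1[KO]·log(fold) + batch offset + N(0, sigma_log²)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    mets = sorted(config.fold_changes)
    n = config.metabolomics_replicates
    samples, conds, batches = [], [], []
    for cond in ("WT", "KO"):
        for j in range(n):
            samples.append(f"{cond}_s{j+1}")
            conds.append(cond)
            batches.append(f"batch{(j % 2) + 1}")
    design = pd.DataFrame({"condition": conds, "batch": batches}, index=samples)

    baselines = np.log(1000.0) + rng.normal(0.0, 1.0, size=len(mets))
    batch_offsets = {
        b: rng.normal(0.0, config.sigma_batch)
        for b in sorted(set(batches))
    }
    log_int = np.empty((len(mets), len(samples)))
    for i, met in enumerate(mets):
        fold = config.fold_changes[met]
        for j, s in enumerate(samples):
            shift = np.log(fold) if conds[j] == "KO" else 0.0
            log_int[i, j] = (
                baselines[i] + shift + batch_offsets[batches[j]]
                + rng.normal(0.0, config.sigma_log)
            )
    intensities = pd.DataFrame(np.exp(log_int), index=mets, columns=samples)
    truth = pd.DataFrame(
        {
            "metabolite_id": mets,
            "fold_change": [config.fold_changes[m] for m in mets],
            "direction": [
                "up" if config.fold_changes[m] > 1
                else ("down" if config.fold_changes[m] < 1 else "unchanged")
                for m in mets
            ],
        }
    )
    return intensities, design, truth


def plant_knockout(
    model: MetabolicModel, exchange_id: str = KNOCKOUT_EXCHANGE
) -> MetabolicModel:
    """Block the reabsorption-style exchange: bounds set to [0, 0]."""
    if exchange_id not in set(model.reaction_ids):
        raise ValueError(f"unknown exchange {exchange_id!r}")
    out = model.copy()
    rxn = out.reaction(exchange_id)
    if rxn.lower_bound == 0.0 and rxn.upper_bound == 0.0:
        import warnings

        warnings.warn(f"{exchange_id} already blocked; no-op", stacklevel=2)
        return out
    rxn.lower_bound = 0.0
    rxn.upper_bound = 0.0
    return out


# ---------------------------------------------------------------------------
# small random networks (property-test workhorse)
# ---------------------------------------------------------------------------


def random_network(
    rng: np.random.Generator,
    n_extra_reactions: int = 4,
    n_internal_metabolites: int = 4,
    max_bound: float = 10.0,
) -> MetabolicModel:
    """A small random feasible network with a positive-optimum demand.

    Skeleton: an uptake exchange feeding a linear chain through all
    internal metabolites into a demand reaction (the objective), plus
    random extra reactions with coefficients in {−2, −1, 1, 2} and random
    bounds containing zero.  The zero flux vector is always feasible and
    the chain guarantees the demand can carry flux.
    """
    m = n_internal_metabolites
    mets = [Metabolite(f"m{i}_c", compartment="c") for i in range(m)]
    rxns = [
        Reaction("EX_in", {"m0_c": -1.0},
                 -float(rng.integers(1, max_bound + 1)), 0.0, "", "boundary")
    ]
    for i in range(m - 1):
        rxns.append(
            Reaction(f"CHAIN{i}", {f"m{i}_c": -1.0, f"m{i+1}_c": 1.0},
                     0.0, float(rng.integers(1, max_bound + 1)), "", "chain")
        )
    rxns.append(
        Reaction("DM_out", {f"m{m-1}_c": -1.0}, 0.0,
                 float(rng.integers(1, max_bound + 1)), "", "boundary")
    )
    for k in range(n_extra_reactions):
        size = int(rng.integers(1, 4))
        picked = rng.choice(m, size=min(size, m), replace=False)
        stoich = {}
        for i in picked:
            coef = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
            stoich[f"m{i}_c"] = coef
        lb = -float(rng.integers(0, max_bound + 1))
        ub = float(rng.integers(0, max_bound + 1))
        rxns.append(Reaction(f"RND{k}", stoich, lb, ub, "", "random"))
    return MetabolicModel(mets, rxns, objective_id="DM_out", id="random_net")
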