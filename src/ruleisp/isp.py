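"""The integrated insulin-signalling-pathway (ISP) model.

Three coupled branches, written as reaction rules over site-graphs:

* **PI3K-AKT** — insulin receptor binding/cycling, IRS1 Tyr phosphorylation,
  IRS1-PI3K complex, PIP2 -> PIP3 conversion, AKT phosphorylation at Thr309
  (PIP3/PDK1-mediated) and Ser474 (mTORC2-mediated), PKC-zeta activation and
  GLUT4 translocation to the plasma membrane.
* **TSC1/2-mTOR** — AMPK, TSC1/2 as the integrator (Ser phosphorylation by
  AMPK activates, Tyr phosphorylation by AKT-pThr inactivates), mTORC1
  activation by amino acids gated by active TSC1/2, p70S6K, plus the PI3K
  variant -> mTORC2 arm.
* **RAS-MAPK** — GRB2/SOS and SHP2 binding to Tyr-phosphorylated IRS1
  (mutually exclusive with each other, GRB2/SOS compatible with PI3K),
  RAS, c-RAF (fully activated by SRC, inactivated by AKT-pSer), MEK1/2 and
  the doubly phosphorylated ERK1/2 output.

Two negative feedback loops close the system: active p70S6K drives IRS1
Ser phosphorylation (which blocks Tyr signalling and disrupts GRB2/SOS and
SHP2 complexes), and doubly phosphorylated ERK1/2 switches off the
catalytic arm of GRB2/SOS.  The ERK feedback acts on the GRB2/SOS catalytic
state only — never on binding occupancy — so it cannot influence the
PI3K-AKT-GLUT4 branch, while the p70S6K feedback acts on IRS1 itself and
reaches both endpoints.

Amounts are molecules/cell (cell volume 3e-12 l); time is minutes.
PDK1 is lumped into the PIP3-dependent AKT Thr-phosphorylation step, and
the phosphatases PTP1B, SHIP2 and PTEN enter as AKT-modulated Hill factors
on the corresponding dephosphorylation rules rather than as explicit
species; with these conventions the generated network closes at exactly
61 species from 42 rules and 101 parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import dialect
from .network import RuleModel

AVOGADRO = 6.02214076e23


class UnitError(ValueError):
    pass


@dataclass(frozen=True)
class UnitContext:
    """Unit-conversion context.

    All amounts are aligned to molecules/cell by multiplying molar
    concentrations by NA*V.  Arbitrary units (AU) are anchored to IRS1,
    which is present in both the AU-denominated and the molecule-denominated
    source inventories; percentage concentrations are mapped to a total
    pool (total GLUT4 and total lipids equal total IRS1; total PKC equals
    total AKT).
    """

    na: float = AVOGADRO
    v: float = 3e-12                  # cell volume, litres
    irs1_molecules: float = 1.0e5     # IRS1 copy number (molecule inventory)
    irs1_au: float = 100.0            # the same amount on the AU scale
    akt_molecules: float = 1.0e5

    @property
    def nav(self) -> float:
        return self.na * self.v

    @property
    def au_scale(self) -> float:
        return self.irs1_molecules / self.irs1_au

    def pool(self, species: str) -> float:
        pools = {
            "GLUT4": self.irs1_molecules,
            "lipids": self.irs1_molecules,
            "PKC": self.akt_molecules,
        }
        try:
            return pools[species]
        except KeyError:
            raise UnitError(
                f"no total pool mapped for percent-denominated species {species!r}"
            ) from None


def convert_concentration(
    value: float,
    unit: str,
    context: UnitContext = UnitContext(),
    species: str | None = None,
) -> float:
    """Convert a concentration to molecules per cell.

    ``molar`` multiplies by NA*V; ``AU`` applies the IRS1 anchor ratio;
    ``percent`` needs a species with a mapped total pool.
    """
    if value < 0:
        raise UnitError("concentration must be non-negative")
    if unit == "molar":
        return value * context.nav
    if unit == "AU":
        return value * context.au_scale
    if unit == "percent":
        if species is None:
            raise UnitError("percent conversion needs the species identity")
        return value / 100.0 * context.pool(species)
    raise UnitError(f"unknown unit {unit!r} (expected molar | AU | percent)")


def nM_to_molecules(dose_nM: float, context: UnitContext = UnitContext()) -> float:
    return convert_concentration(dose_nM * 1e-9, "molar", context)


# ---------------------------------------------------------------------------
# model text
# ---------------------------------------------------------------------------

# The named feedback loops, as explicit rule subsets.
FEEDBACK_RULES = {
    "p70S6K-IRS1": ["irs1_ser_phos_by_p70"],
    "ERK1/2-GRB2/SOS": ["gs_inhibition_by_erk"],
}

# Strengthened ERK->GRB2/SOS feedback (x10), exposed as a named perturbation
# rather than changing the literature default.
NAMED_PERTURBATIONS = {
    "strong_erk_gs_feedback": ("kcat39", 10.0),
    "enhanced_p70_feedback": ("k15", 2.0),
}


def _model_text(context: UnitContext, insulin_molecules: float) -> str:
    c = context
    # Listed initial conditions = the insulin-free resting state of the model
    # (amino acids present): no simulation starts mid-transient, so a zero
    # dose leaves every trajectory flat.  Pool sizes follow the conversion
    # scheme (IRS1 anchor, AU scale, percent pools); the phospho-form splits
    # are the resting-state fractions of those pools.
    seeds = {
        # all receptors at the plasma membrane at rest (internalization is
        # phosphorylation-gated)
        "IR(loc~mem,ins~0,Y~0)": 1.0e5,
        # IRS1 is the AU/molecule anchor; basal Ser phosphorylation (PKC/p70
        # basal tone) holds ~42 % of IRS1 in the Ser-phosphorylated state
        "IRS1(Y~0,S~0,pi3k,gs,shp2)": 0.582970 * c.irs1_molecules,
        "IRS1(Y~0,S~P,pi3k,gs,shp2)": 0.417030 * c.irs1_molecules,
        "PI3K(irs)": 1.0e5,
        "GS(irs,cat~on)": 10.0 * c.au_scale,
        "SHP2(irs)": 10.0 * c.au_scale,
        # lipid pool equals the IRS1 pool; all PI(4,5)P2 at rest
        "LIPID(s~pip2)": c.irs1_molecules,
        "AKT(T~0,S~0)": c.akt_molecules,
        # PKC pool equals the AKT pool
        "PKC(T~0)": c.akt_molecules,
        # GLUT4 pool equals the IRS1 pool; 96 % cytosolic at rest
        "GLUT4(loc~cyt)": 0.96 * c.irs1_molecules,
        "GLUT4(loc~mem)": 0.04 * c.irs1_molecules,
        # basal energy signalling keeps AMPK and TSC1/2 fully active
        "AMPK(T~P)": 10.0 * c.au_scale,
        "TSC(S~P,Y~0)": 10.0 * c.au_scale,
        # amino acids alone sustain ~10 % mTORC1 and ~14 % p70S6K activity
        "MTORC1(S~0)": 0.896057 * 30.0 * c.au_scale,
        "MTORC1(S~P)": 0.103943 * 30.0 * c.au_scale,
        "P70(T~0)": 0.857373 * 40.0 * c.au_scale,
        "P70(T~P)": 0.142627 * 40.0 * c.au_scale,
        "PI3KV(s~i)": 10.0 * c.au_scale,
        "MTORC2(s~i)": 18.8 * c.au_scale,   # 18.8 AU, via the IRS1 anchor
        "SRC(s~i)": 10.0 * c.au_scale,
        "RAS(s~GDP)": 20.0 * c.au_scale,
        "RAF(s~i)": 10.0 * c.au_scale,
        "MEK(S~0)": 50.0 * c.au_scale,
        "ERK(T~0,Y~0)": 50.0 * c.au_scale,
    }
    seed_lines = "\n".join(f"  {s} {v!r}" for s, v in seeds.items())

    return f"""
begin molecule types
  INS()
  IR(loc~mem~cyt,ins~0~1~2,Y~0~P)
  IRS1(Y~0~P,S~0~P,pi3k,gs,shp2)
  PI3K(irs)
  GS(irs,cat~on~off)
  SHP2(irs)
  LIPID(s~pip2~pip3)
  AKT(T~0~P,S~0~P)
  PKC(T~0~P)
  GLUT4(loc~cyt~mem)
  AMPK(T~0~P)
  TSC(S~0~P,Y~0~P)
  AA()
  MTORC1(S~0~P)
  P70(T~0~P)
  PI3KV(s~i~a)
  MTORC2(s~i~a)
  SRC(s~i~a)
  RAS(s~GDP~GTP)
  RAF(s~i~a)
  MEK(S~0~P)
  ERK(T~0~P,Y~0~P)
end molecule types

begin parameters
  k1 3.3210e-05
  k_1 0.4
  k2 3.3210e-05
  k_2 4.0
  k_3 0.2
  k4p 0.05
  k6 1.0
  k_4 0.5
  k7 3.5e-05
  k_7 1.5
  Kd_akt 5.0e4
  n_akt 1.5
  k7p 0.02
  k_7p 0.3
  Vmax 0.35
  Kd_pkc 4.0e4
  n 2.0
  k15 4.0
  Kd_p70 9.0e3
  n_p70 4.0
  k8 1.0e-05
  k_8 0.5
  k40 2.0e-05
  k_40 0.1
  k42 2.0e-05
  k_42 0.1
  k41 2.0
  k9a 6.0e-06
  k9s 4.0
  k11 4.0
  Kd_pip3 5.0e3
  k_11 1.0
  k19 3.0
  Kd_mt2 9.0e3
  k_19 1.0
  k12 2.0
  k_12 0.5
  k13 0.0020833
  k_13 0.05
  k13p 0.08
  Kd_g4 6.0e4
  n_akt4 2.0
  k13p2 0.02
  k14 96.0
  k_14 0.001
  k16 0.5
  k_16 1.5
  Kd_irs 3.0e4
  n_irs 2.0
  k21 1.0
  Kd_ampk 5.0e3
  n_ampk 2.0
  k22 0.5
  k_21 0.18
  Kd_aktT 4.0e4
  n_aktT 1.0
  k_22 0.1
  k17 0.3
  Kd_aa 5.0e4
  n_aa 1.0
  k18 2.0
  Kd_tsc 4.0e3
  n_tsc 2.0
  k20 0.3
  Kd_mt1 2.5e4
  k_20 0.2
  k23 2.0
  Kd_irm 4.0e4
  k_23 0.5
  k24 2.0
  Kd_p3v 5.0e3
  k_24 0.5
  kcat24 0.3
  Kd_src 8.0e4
  n_src 1.0
  kcat25 0.5
  alpha24 1.0e-05
  kcat27 1.0
  kcat28 0.8
  Kd_gs 6.0e3
  n_gs 2.0
  kcat29 0.3
  kcat30 3.0
  Kd_ras 8.0e3
  n_ras 2.0
  kcat31 1.0e-06
  kcat32 4.0e-05
  kcat33 1.0
  Kd_raf 4.0e3
  n_raf 2.0
  kcat34 0.8
  kcat35 1.5
  Kd_mek 2.5e4
  n_mek 2.0
  kcat36 1.5
  kcat37 0.6
  kcat38 0.6
  kcat39 0.8
  Kd_erk 3.0e4
  n_erk 2.0
  k_39 0.05
end parameters

begin seed species
  $INS() {insulin_molecules!r}
  $AA() 1.0e5
{seed_lines}
end seed species

begin observables
  IR_phos IR(Y~P)
  IR_phos_mem IR(loc~mem,Y~P)
  IRS1_pY IRS1(Y~P)
  pIRS1_Ser IRS1(S~P)
  IRS1_PI3K IRS1(pi3k!1).PI3K(irs!1)
  PIP3 LIPID(s~pip3)
  pAKT_T309 AKT(T~P)
  pAKT_S473 AKT(S~P)
  AKT_act AKT(T~P) AKT(T~0,S~P)
  PKC_act PKC(T~P)
  GLUT4_drivers_akt AKT(T~P) AKT(T~0,S~P)
  GLUT4_mem GLUT4(loc~mem)
  GLUT4_cyt GLUT4(loc~cyt)
  AMPK_act AMPK(T~P)
  TSC_act TSC(S~P,Y~0)
  AA_level AA()
  pmTOR_S2448 MTORC1(S~P)
  pP70S6K_T389 P70(T~P)
  PI3Kv_act PI3KV(s~a)
  mTORC2_act MTORC2(s~a)
  GS_IRS1 IRS1(gs!1).GS(irs!1)
  GS_IRS1_active IRS1(gs!1).GS(irs!1,cat~on)
  SHP2_IRS1 IRS1(shp2!1).SHP2(irs!1)
  RAS_GTP RAS(s~GTP)
  RAF_act RAF(s~a)
  MEK_P MEK(S~P)
  ppERK ERK(T~P,Y~P)
end observables

begin reaction rules
  ins_binding_1: IR(loc~mem,ins~0,Y~0) + INS() <-> IR(loc~mem,ins~1,Y~P) ma(k1), ma(k_1)
  ins_binding_2: IR(loc~mem,ins~1,Y~P) + INS() <-> IR(loc~mem,ins~2,Y~P) ma(k2), ma(k_2)
  ir_surface_dephos: IR(loc~mem,Y~P) -> IR(loc~mem,ins~0,Y~0) ma(k_3)
  ir_internalization: IR(loc~mem,Y~P) -> IR(loc~cyt,ins~0,Y~P) ma(k4p)
  ir_internal_dephos: IR(loc~cyt,Y~P) -> IR(loc~cyt,Y~0) ma(k6)
  ir_externalization: IR(loc~cyt,ins~0,Y~0) -> IR(loc~mem,ins~0,Y~0) ma(k_4)
  irs1_tyr_phos: IR(Y~P) + IRS1(Y~0,S~0) -> IR(Y~P) + IRS1(Y~P,S~0) ma(k7)
  irs1_tyr_dephos: IRS1(Y~P,pi3k,gs,shp2) -> IRS1(Y~0,pi3k,gs,shp2) ihill(k_7; AKT_act; Kd_akt; n_akt)
  irs1_ser_basal: IRS1(S~0) <-> IRS1(S~P) ma(k7p), ma(k_7p)
  irs1_ser_phos_by_pkc: IRS1(S~0) -> IRS1(S~P) hill(Vmax; PKC_act; Kd_pkc; n)
  irs1_ser_phos_by_p70: IRS1(S~0) -> IRS1(S~P) hill(Vmax*k15; pP70S6K_T389; Kd_p70; n_p70)
  pi3k_binding: IRS1(Y~P,S~0,pi3k,shp2) + PI3K(irs) <-> IRS1(Y~P,pi3k!1,shp2).PI3K(irs!1) ma(k8), ma(k_8)
  gs_binding: IRS1(Y~P,S~0,gs,shp2) + GS(irs) <-> IRS1(Y~P,gs!1,shp2).GS(irs!1) ma(k40), ma(k_40)
  shp2_binding: IRS1(Y~P,S~0,pi3k,gs,shp2) + SHP2(irs) <-> IRS1(Y~P,pi3k,gs,shp2!1).SHP2(irs!1) ma(k42), ma(k_42)
  gs_release_on_ser: IRS1(S~P,gs!1).GS(irs!1) -> IRS1(S~P,gs) + GS(irs) ma(k41)
  shp2_release_on_ser: IRS1(S~P,shp2!1).SHP2(irs!1) -> IRS1(S~P,shp2) + SHP2(irs) ma(k41)
  pip3_synthesis: IRS1(S~0,pi3k!1).PI3K(irs!1) + LIPID(s~pip2) -> IRS1(S~0,pi3k!1).PI3K(irs!1) + LIPID(s~pip3) ma(k9a)
  pip3_degradation: LIPID(s~pip3) -> LIPID(s~pip2) ihill(k9s; AKT_act; Kd_akt; n_akt)
  akt_thr_phos: AKT(T~0) <-> AKT(T~P) hill(k11; PIP3; Kd_pip3; 1.0), ma(k_11)
  akt_ser_phos: AKT(S~0) <-> AKT(S~P) hill(k19; mTORC2_act; Kd_mt2; 1.0), ma(k_19)
  pkc_activation: PKC(T~0) <-> PKC(T~P) hill(k12; PIP3; Kd_pip3; 1.0), ma(k_12)
  glut4_basal_translocation: GLUT4(loc~cyt) <-> GLUT4(loc~mem) ma(k13), ma(k_13)
  glut4_stim_by_akt: GLUT4(loc~cyt) -> GLUT4(loc~mem) hill(k13p; GLUT4_drivers_akt; Kd_g4; n_akt4)
  glut4_stim_by_pkc: GLUT4(loc~cyt) -> GLUT4(loc~mem) hill(k13p2; PKC_act; Kd_g4; n_akt4)
  glut4_turnover: 0 <-> GLUT4(loc~cyt) ma(k14), ma(k_14)
  ampk_activation: AMPK(T~0) <-> AMPK(T~P) ma(k16), hill(k_16; IRS1_pY; Kd_irs; n_irs)
  tsc_ser_phos: TSC(S~0,Y~0) <-> TSC(S~P,Y~0) hill(k21; AMPK_act; Kd_ampk; n_ampk), hill(k22; pAKT_T309; Kd_aktT; n_aktT)
  tsc_tyr_phos: TSC(S~0,Y~0) <-> TSC(S~0,Y~P) hill(k_21; pAKT_T309; Kd_aktT; n_aktT), ma(k_22)
  mtorc1_activation: MTORC1(S~0) <-> MTORC1(S~P) hill(k17; AA_level; Kd_aa; n_aa), hill(k18; TSC_act; Kd_tsc; n_tsc)
  p70_activation: P70(T~0) <-> P70(T~P) hill(k20; pmTOR_S2448; Kd_mt1; 1.0), ma(k_20)
  pi3kv_activation: PI3KV(s~i) <-> PI3KV(s~a) hill(k23; IR_phos_mem; Kd_irm; 1.0), ma(k_23)
  mtorc2_activation: MTORC2(s~i) <-> MTORC2(s~a) hill(k24; PI3Kv_act; Kd_p3v; 1.0), ma(k_24)
  src_activation: SRC(s~i) <-> SRC(s~a) hill(kcat24; IR_phos; Kd_src; n_src), ma(kcat25)
  src_activation_via_shp2: IRS1(shp2!1).SHP2(irs!1) + SRC(s~i) -> IRS1(shp2!1).SHP2(irs!1) + SRC(s~a) ma(alpha24)
  ras_activation: RAS(s~GDP) <-> RAS(s~GTP) hill(kcat28; GS_IRS1_active; Kd_gs; n_gs), ma(kcat27)
  raf_activation: RAF(s~i) <-> RAF(s~a) hill(kcat30; RAS_GTP; Kd_ras; n_ras), ma(kcat29)
  raf_full_activation_by_src: SRC(s~a) + RAF(s~i) -> SRC(s~a) + RAF(s~a) ma(kcat31)
  raf_inactivation_by_akt: AKT(S~P) + RAF(s~a) -> AKT(S~P) + RAF(s~i) ma(kcat32)
  mek_phosphorylation: MEK(S~0) <-> MEK(S~P) hill(kcat33; RAF_act; Kd_raf; n_raf), ma(kcat34)
  erk_phos_thr: ERK(T~0,Y~0) <-> ERK(T~P,Y~0) hill(kcat35; MEK_P; Kd_mek; n_mek), ma(kcat38)
  erk_phos_tyr: ERK(T~P,Y~0) <-> ERK(T~P,Y~P) hill(kcat36; MEK_P; Kd_mek; n_mek), ma(kcat37)
  gs_inhibition_by_erk: GS(cat~on) <-> GS(cat~off) hill(kcat39; ppERK; Kd_erk; n_erk), ma(k_39)
end reaction rules
"""


def build_isp_model(
    context: UnitContext = UnitContext(),
    insulin_nM: float = 0.0,
) -> RuleModel:
    """Build the fully validated ISP model.

    Insulin and amino acids are constant input species; the default build
    has no insulin (the stimulation protocol sets the dose).  Initial
    amounts follow the unit-conversion scheme anchored on IRS1 (see
    :class:`UnitContext`): receptor, IRS1 and PI3K pools on the molecule
    inventory, mTOR-branch pools on the AU scale, GLUT4/lipid/PKC pools as
    percentages of their mapped totals.
    """
    if insulin_nM < 0:
        raise UnitError("insulin dose must be non-negative")
    text = _model_text(context, nM_to_molecules(insulin_nM, context))
    model = dialect.loads(text, name="isp")
    model.validate()
    return model


# canonical output observables reported by simulations
STANDARD_OUTPUTS = [
    "pAKT_S473",
    "ppERK",
    "pmTOR_S2448",
    "pP70S6K_T389",
    "GLUT4_mem",
]


def packaged_model_path():
    """Path of the shipped model file (dialect text)."""
    from importlib.resources import files

    return files("ruleisp").joinpath("data/isp_model.rbl")


def load_packaged_model() -> RuleModel:
    """Load the shipped ISP model from its packaged dialect text.

    Equivalent to :func:`build_isp_model` with default context and zero
    insulin; the equivalence is asserted by the test suite.
    """
    text = packaged_model_path().read_text()
    model = dialect.loads(text, name="isp")
    model.validate()
    return model
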