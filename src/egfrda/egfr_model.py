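"""Builder for the EGFR signal-transduction network.

The model follows the canonical EGFR scheme: EGF binds EGFR at the
plasma membrane, liganded receptors dimerize and autophosphorylate;
phospho-receptor docks the adaptors Grb2 (G), Shc (S), RasGAP (R),
Shp2 (H), Plcgamma1 (P), Cbl (C) and Gab1 (A) and phosphorylates its
docked substrates; Grb2-docked receptor activates Sos, driving the Ras
GDP/GTP cycle (reversed by receptor-docked RasGAP) and the
Raf -> MEK -> ERK cascade; Src activates and phosphorylates Hrs and Cbl;
phospho-Cbl ubiquitinates internalized receptor, phospho-Hrs sorts
ubiquitinated receptor from endosome to lysosome where it is degraded;
Gab1-bound PI3K converts PIP2 to PIP3; every phospho-state has a
first-order dephosphorylation.  Endosomal receptor keeps signaling:
it binds and phosphorylates the same adaptors as the plasma-membrane
pool.

Parameter partition
-------------------
Every parameter carries a group tag plus two flags.  On the default
(full) network the flags partition the 118 parameters as:

* 102 ``wt_optimized`` -- free in the wild-type estimation;
* 54 of those ``mutant_variable`` -- additionally free when re-fitting
  the Y992F mutant (12 initial abundances, 18 receptor binding /
  dissociation constants, 5 receptor-catalyzed phosphorylation rates,
  14 dephosphorylation rates, 5 receptor-trafficking rates);
* 16 fixed constants (Michaelis constants and downstream substrate
  pools), so a mutant re-fit holds 64 parameters at their WT values.

Default rate constants are order-of-magnitude values (association
~5e-3-5e-2 per au per min, dissociation ~0.1-4 per min, catalysis
~0.2-5 per min, Km ~1e1-1e2 au, abundances 30-100 au), tuned once to
the qualitative WT response; they serve as centers of the estimation
priors.  Three regime choices matter for identifiability -- avid
docking, kcat-limited substrate release, competitive dimer
dissociation; see docs/methods.md.
"""

from __future__ import annotations

from .network import (
    Component,
    NetworkValidationError,
    Observable,
    Parameter,
    Reaction,
    ReactionNetwork,
    Species,
)

#: adaptor key -> (species id, full protein name)
ADAPTORS = {
    "G": ("G", "Grb2"),
    "S": ("S", "Shc"),
    "R": ("R", "RasGAP"),
    "H": ("H", "Shp2"),
    "P": ("P", "Plcg1"),
    "C": ("C", "Cbl"),
    "A": ("A", "Gab1"),
}

#: adaptors that are phosphorylated (and released) by the receptor kinase
RECEPTOR_SUBSTRATES = ("S", "H", "P", "C", "A")

OPTIONAL_BLOCKS = ("mapk", "endosomal_signaling")

#: the seven proteins observed in the SILAC time courses
OBSERVED_PROTEINS = ("EGFR", "Shc", "Plcg1", "Hrs", "Cbl", "Shp2", "ERK1")

PROTEIN_OBSERVABLE = {
    "EGFR": "pEGFR_total",
    "Shc": "pShc",
    "Plcg1": "pPlcg1",
    "Hrs": "pHrs",
    "Cbl": "pCbl",
    "Shp2": "pShp2",
    "ERK1": "pERK1",
}


class ConfigurationError(ValueError):
    pass


def _c(base, *mods):
    return Component(base, frozenset(mods))


def _dimer_components(phospho, ub=False):
    mods = set()
    if phospho:
        mods.add("p")
    if ub:
        mods.add("ub")
    er = Component("Er", frozenset(mods))
    return (_c("E"), _c("E"), er, er)


def build_egfr_network(blocks=None) -> ReactionNetwork:
    """Build the EGFR network.  ``blocks`` selects the optional blocks
    (default: all of ``mapk``, ``endosomal_signaling``)."""
    if blocks is None:
        blocks = set(OPTIONAL_BLOCKS)
    blocks = set(blocks)
    unknown = blocks - set(OPTIONAL_BLOCKS)
    if unknown:
        raise ConfigurationError(f"unknown model blocks: {sorted(unknown)}")
    mapk = "mapk" in blocks
    endo = "endosomal_signaling" in blocks

    net = ReactionNetwork(name="egfr_y992f")

    def sp(sid, compartment, components):
        return net.add_species(Species(sid, compartment, tuple(components)))

    def par(pid, value, role="rate_constant", group="other",
            opt=True, mut=False):
        return net.add_parameter(Parameter(pid, value, role, group, opt, mut))

    def rxn(rid, reactants, products, law, params, modifiers=()):
        return net.add_reaction(Reaction(rid, reactants, products, law,
                                         tuple(params), tuple(modifiers)))

    # ------------------------------------------------------------------ species
    sp("E_ex", "EX", [_c("E")])
    sp("Er_pm", "PM", [_c("Er")])
    sp("E.Er_pm", "PM", [_c("E"), _c("Er")])
    sp("Er2_0_pm", "PM", [_c("Er"), _c("Er")])
    sp("Er2_pm", "PM", _dimer_components(False))
    sp("Er2p_pm", "PM", _dimer_components(True))
    for key, (sid, _) in ADAPTORS.items():
        sp(f"Er2p.{key}_pm", "PM", _dimer_components(True) + (_c(sid),))
    sp("Er2p_en", "EN", _dimer_components(True))
    sp("Er2_en", "EN", _dimer_components(False))
    sp("Er2pub_en", "EN", _dimer_components(True, ub=True))
    if endo:
        for key, (sid, _) in ADAPTORS.items():
            sp(f"Er2p.{key}_en", "EN", _dimer_components(True) + (_c(sid),))
    sp("Er2pub_ly", "LY", _dimer_components(True, ub=True))
    sp("Er_deg", "CY", [_c("Er")])
    sp("E_deg", "CY", [_c("E")])

    for key, (sid, _) in ADAPTORS.items():
        sp(sid, "CY", [_c(sid)])
    for key in RECEPTOR_SUBSTRATES:
        sid = ADAPTORS[key][0]
        sp(f"{sid}p", "CY", [_c(sid, "p")])
    sp("Sp.G", "CY", [_c("S", "p"), _c("G")])
    sp("O", "CY", [_c("O")])
    sp("Oa", "CY", [_c("O", "active")])
    sp("G.O", "CY", [_c("G"), _c("O")])
    sp("Ap.I", "CY", [_c("A", "p"), _c("I")])
    sp("I", "CY", [_c("I")])
    sp("Hr", "CY", [_c("Hr")])
    sp("Hrp", "CY", [_c("Hr", "p")])
    sp("Sr", "CY", [_c("Sr")])
    sp("Sra", "CY", [_c("Sr", "active")])
    sp("PIP2", "CY", [_c("P2")])
    sp("PIP3", "CY", [_c("P2", "p")])
    sp("IP3", "CY", [_c("P2", "ip3")])
    if mapk:
        sp("RasGDP", "CY", [_c("RsD")])
        sp("RasGTP", "CY", [_c("RsD", "active")])
        sp("Raf", "CY", [_c("Raf")])
        sp("Rafa", "CY", [_c("Raf", "active")])
        sp("MEK", "CY", [_c("MEK")])
        sp("MEKp", "CY", [_c("MEK", "pt")])
        sp("MEKpp", "CY", [_c("MEK", "pt", "pt2")])
        sp("ERK", "CY", [_c("ERK")])
        sp("ERKp", "CY", [_c("ERK", "pt")])
        sp("ERKpp", "CY", [_c("ERK", "pt", "pt2")])

    # --------------------------------------------------------- initial abundances
    # the 12 signaling-protein abundances are mutant-variable
    abundances = {
        "Er_pm": ("init_egfr", 100.0),
        "G": ("init_grb2", 80.0),
        "S": ("init_shc", 80.0),
        "R": ("init_rasgap", 30.0),
        "H": ("init_shp2", 60.0),
        "P": ("init_plcg1", 50.0),
        "O": ("init_sos", 30.0),
        "C": ("init_cbl", 40.0),
        "A": ("init_gab1", 40.0),
        "I": ("init_pi3k", 40.0),
        "Hr": ("init_hrs", 30.0),
        "Sr": ("init_src", 50.0),
    }
    for sid, (pid, v) in abundances.items():
        par(pid, v, role="initial_abundance", group="abundance", opt=True, mut=True)
        net.initial_abundance[sid] = pid
    # downstream substrate pools: fixed constants
    pools = {"PIP2": ("init_pip2", 500.0)}
    if mapk:
        pools.update({
            "RasGDP": ("init_rasgdp", 120.0),
            "Raf": ("init_raf", 100.0),
            "MEK": ("init_mek", 200.0),
            "ERK": ("init_erk", 200.0),
        })
    for sid, (pid, v) in pools.items():
        par(pid, v, role="initial_abundance", group="abundance", opt=False)
        net.initial_abundance[sid] = pid

    # ------------------------------------------------------------- receptor core
    par("k_egf_on", 1e-2, group="binding", mut=True)
    par("k_egf_off", 0.1, group="dissociation", mut=True)
    rxn("r_egf_bind", {"E_ex": 1, "Er_pm": 1}, {"E.Er_pm": 1},
        "mass_action_reversible", ["k_egf_on", "k_egf_off"])
    par("k_dim_on", 5e-2, group="binding", mut=True)
    # dimer dissociation competes with autophosphorylation (k_auto), so its
    # value shapes the activated-receptor yield
    par("k_dim_off", 4.0, group="dissociation", mut=True)  # EGFR_dimer_dissociation
    rxn("r_dimerize", {"E.Er_pm": 2}, {"Er2_pm": 1},
        "mass_action_reversible", ["k_dim_on", "k_dim_off"])
    par("k_dim0_on", 1e-4, group="binding")
    par("k_dim0_off", 1.0, group="dissociation")
    rxn("r_predimer", {"Er_pm": 2}, {"Er2_0_pm": 1},
        "mass_action_reversible", ["k_dim0_on", "k_dim0_off"])
    par("k_auto", 5.0, group="phosphorylation")
    rxn("r_autophos", {"Er2_pm": 1}, {"Er2p_pm": 1},
        "mass_action_irreversible", ["k_auto"])
    par("kdp_egfr_pm", 0.5, group="dephosphorylation", mut=True)
    rxn("r_dephos_egfr_pm", {"Er2p_pm": 1}, {"Er2_pm": 1},
        "mass_action_irreversible", ["kdp_egfr_pm"])

    # --------------------------------------------------- adaptor docking (PM, EN)
    # avid docking: the activated receptor, not the adaptor pool, is the
    # scarce resource, so adaptors compete for it
    binding_defaults = {"G": 2e-2, "S": 2e-2, "R": 5e-3, "H": 2e-2,
                        "P": 2e-2, "C": 5e-3, "A": 5e-3}
    for key, (sid, name) in ADAPTORS.items():
        lname = name.lower()
        par(f"k_bind_{lname}", binding_defaults[key], group="binding", mut=True)
        par(f"k_rel_{lname}", 1.0, group="dissociation", mut=True)
        rxn(f"r_bind_{lname}_pm", {"Er2p_pm": 1, sid: 1}, {f"Er2p.{key}_pm": 1},
            "mass_action_reversible", [f"k_bind_{lname}", f"k_rel_{lname}"])
        if endo:
            par(f"k_bind_{lname}_en", binding_defaults[key], group="binding")
            par(f"k_rel_{lname}_en", 0.1, group="dissociation")
            rxn(f"r_bind_{lname}_en", {"Er2p_en": 1, sid: 1}, {f"Er2p.{key}_en": 1},
                "mass_action_reversible", [f"k_bind_{lname}_en", f"k_rel_{lname}_en"])

    # ------------------------------- receptor-catalyzed substrate phosphorylation
    # docked substrate is phosphorylated and released (catalytic release)
    for key in RECEPTOR_SUBSTRATES:
        sid, name = ADAPTORS[key]
        lname = name.lower()
        par(f"kcat_phos_{lname}", 0.2, group="phosphorylation", mut=True)
        rxn(f"r_phos_{lname}_pm", {f"Er2p.{key}_pm": 1}, {"Er2p_pm": 1, f"{sid}p": 1},
            "mass_action_irreversible", [f"kcat_phos_{lname}"])
        if endo:
            par(f"kcat_phos_{lname}_en", 0.2, group="phosphorylation")
            rxn(f"r_phos_{lname}_en", {f"Er2p.{key}_en": 1}, {"Er2p_en": 1, f"{sid}p": 1},
                "mass_action_irreversible", [f"kcat_phos_{lname}_en"])

    # ------------------------------------------------ cytosolic dephosphorylation
    dephos_defaults = {"S": 0.35, "H": 0.35, "P": 0.35, "C": 0.25, "A": 0.35}
    for key in RECEPTOR_SUBSTRATES:
        sid, name = ADAPTORS[key]
        lname = name.lower()
        par(f"kdp_{lname}", dephos_defaults[key], group="dephosphorylation", mut=True)
        rxn(f"r_dephos_{lname}", {f"{sid}p": 1}, {sid: 1},
            "mass_action_irreversible", [f"kdp_{lname}"])
    par("kdp_hrs", 0.25, group="dephosphorylation", mut=True)
    rxn("r_dephos_hrs", {"Hrp": 1}, {"Hr": 1},
        "mass_action_irreversible", ["kdp_hrs"])

    # ------------------------------------------------------------------ Src arm
    par("k_src_act", 1e-2, group="other")
    rxn("r_src_act", {"Sr": 1}, {"Sra": 1},
        "mass_action_irreversible", ["k_src_act"], modifiers=["Er2p_pm"])
    par("k_src_deact", 0.1, group="other")
    rxn("r_src_deact", {"Sra": 1}, {"Sr": 1},
        "mass_action_irreversible", ["k_src_deact"])
    par("k_phos_hrs", 2e-2, group="phosphorylation")
    rxn("r_phos_hrs", {"Hr": 1}, {"Hrp": 1},
        "mass_action_irreversible", ["k_phos_hrs"], modifiers=["Sra"])
    par("k_phos_cbl_src", 1e-2, group="phosphorylation")
    rxn("r_phos_cbl_src", {"C": 1}, {"Cp": 1},
        "mass_action_irreversible", ["k_phos_cbl_src"], modifiers=["Sra"])

    # ------------------------------------------------- trafficking / degradation
    par("k_int", 0.08, group="internalization", mut=True)
    rxn("r_internalize", {"Er2p_pm": 1}, {"Er2p_en": 1},
        "mass_action_irreversible", ["k_int"])
    par("k_int0", 5e-3, group="internalization")
    rxn("r_internalize_0", {"Er2_pm": 1}, {"Er2_en": 1},
        "mass_action_irreversible", ["k_int0"])
    par("k_rec", 0.05, group="other")
    rxn("r_recycle_p", {"Er2p_en": 1}, {"Er2p_pm": 1},
        "mass_action_irreversible", ["k_rec"])
    rxn("r_recycle", {"Er2_en": 1}, {"Er2_pm": 1},
        "mass_action_irreversible", ["k_rec"])
    par("kdp_egfr_en", 0.5, group="dephosphorylation", mut=True)
    rxn("r_dephos_egfr_en", {"Er2p_en": 1}, {"Er2_en": 1},
        "mass_action_irreversible", ["kdp_egfr_en"])
    par("k_ub", 1.0, group="ubiquitination", mut=True)
    par("km_ub", 10.0, role="michaelis_constant", group="ubiquitination", opt=False)
    rxn("r_ubiquitinate", {"Er2p_en": 1}, {"Er2pub_en": 1},
        "michaelis_menten", ["k_ub", "km_ub"], modifiers=["Cp"])
    par("k_deub", 0.05, group="deubiquitination", mut=True)
    rxn("r_deubiquitinate", {"Er2pub_en": 1}, {"Er2p_en": 1},
        "mass_action_irreversible", ["k_deub"])
    par("k_sort", 0.5, group="degradation", mut=True)
    par("km_sort", 10.0, role="michaelis_constant", group="degradation", opt=False)
    rxn("r_sort", {"Er2pub_en": 1}, {"Er2pub_ly": 1},
        "michaelis_menten", ["k_sort", "km_sort"], modifiers=["Hrp"])
    par("k_deg", 0.2, group="degradation", mut=True)
    rxn("r_degrade", {"Er2pub_ly": 1}, {"Er_deg": 2, "E_deg": 2},
        "mass_action_irreversible", ["k_deg"])

    # -------------------------------------------------------- Shc/Grb2/Sos wiring
    par("k_shc_grb_on", 2e-3, group="binding")
    par("k_shc_grb_off", 0.1, group="dissociation")
    rxn("r_shc_grb", {"Sp": 1, "G": 1}, {"Sp.G": 1},
        "mass_action_reversible", ["k_shc_grb_on", "k_shc_grb_off"])
    par("k_grb_sos_on", 2e-3, group="binding")
    par("k_grb_sos_off", 0.1, group="dissociation")
    rxn("r_grb_sos", {"G": 1, "O": 1}, {"G.O": 1},
        "mass_action_reversible", ["k_grb_sos_on", "k_grb_sos_off"])
    sos_sites = ["Er2p.G_pm", "Sp.G"]
    if endo:
        sos_sites.append("Er2p.G_en")
    par("k_sos_act", 5e-2, group="other")
    rxn("r_sos_act", {"O": 1}, {"Oa": 1},
        "mass_action_irreversible", ["k_sos_act"], modifiers=sos_sites)
    par("k_sos_deact", 0.5, group="other")
    rxn("r_sos_deact", {"Oa": 1}, {"O": 1},
        "mass_action_irreversible", ["k_sos_deact"])

    # --------------------------------------------------------------- MAPK cascade
    if mapk:
        par("k_fb_sos", 0.3, group="other")
        rxn("r_sos_feedback", {"Oa": 1}, {"O": 1},
            "mass_action_irreversible", ["k_fb_sos"], modifiers=["ERKpp"])
        par("kcat_ras", 10.0, group="other")
        par("km_ras", 100.0, role="michaelis_constant", opt=False)
        rxn("r_ras_load", {"RasGDP": 1}, {"RasGTP": 1},
            "michaelis_menten", ["kcat_ras", "km_ras"], modifiers=["Oa"])
        gap_sites = ["Er2p.R_pm"] + (["Er2p.R_en"] if endo else [])
        par("kcat_gap", 5.0, group="other")
        par("km_gap", 100.0, role="michaelis_constant", opt=False)
        rxn("r_ras_gap", {"RasGTP": 1}, {"RasGDP": 1},
            "michaelis_menten", ["kcat_gap", "km_gap"], modifiers=gap_sites)
        par("k_rst_basal", 0.1, group="other")
        rxn("r_ras_basal", {"RasGTP": 1}, {"RasGDP": 1},
            "mass_action_irreversible", ["k_rst_basal"])
        par("kcat_raf", 4.0, group="other")
        par("km_raf", 100.0, role="michaelis_constant", opt=False)
        rxn("r_raf_act", {"Raf": 1}, {"Rafa": 1},
            "michaelis_menten", ["kcat_raf", "km_raf"], modifiers=["RasGTP"])
        par("kdp_raf", 0.3, group="dephosphorylation", mut=True)
        rxn("r_raf_deact", {"Rafa": 1}, {"Raf": 1},
            "mass_action_irreversible", ["kdp_raf"])
        par("kcat_mek1", 4.0, group="other")
        par("km_mek1", 100.0, role="michaelis_constant", opt=False)
        rxn("r_mek_p1", {"MEK": 1}, {"MEKp": 1},
            "michaelis_menten", ["kcat_mek1", "km_mek1"], modifiers=["Rafa"])
        par("kcat_mek2", 4.0, group="other")
        par("km_mek2", 100.0, role="michaelis_constant", opt=False)
        rxn("r_mek_p2", {"MEKp": 1}, {"MEKpp": 1},
            "michaelis_menten", ["kcat_mek2", "km_mek2"], modifiers=["Rafa"])
        par("kdp_mek1", 0.5, group="dephosphorylation", mut=True)
        rxn("r_mek_dp1", {"MEKp": 1}, {"MEK": 1},
            "mass_action_irreversible", ["kdp_mek1"])
        par("kdp_mek2", 0.5, group="dephosphorylation", mut=True)
        rxn("r_mek_dp2", {"MEKpp": 1}, {"MEKp": 1},
            "mass_action_irreversible", ["kdp_mek2"])
        par("kcat_erk1", 4.0, group="other")
        par("km_erk1", 100.0, role="michaelis_constant", opt=False)
        rxn("r_erk_p1", {"ERK": 1}, {"ERKp": 1},
            "michaelis_menten", ["kcat_erk1", "km_erk1"], modifiers=["MEKpp"])
        par("kcat_erk2", 4.0, group="other")
        par("km_erk2", 100.0, role="michaelis_constant", opt=False)
        rxn("r_erk_p2", {"ERKp": 1}, {"ERKpp": 1},
            "michaelis_menten", ["kcat_erk2", "km_erk2"], modifiers=["MEKpp"])
        par("kdp_erk1", 0.8, group="dephosphorylation", mut=True)
        rxn("r_erk_dp1", {"ERKp": 1}, {"ERK": 1},
            "mass_action_irreversible", ["kdp_erk1"])
        par("kdp_erk2", 0.8, group="dephosphorylation", mut=True)
        rxn("r_erk_dp2", {"ERKpp": 1}, {"ERKp": 1},
            "mass_action_irreversible", ["kdp_erk2"])

    # ---------------------------------------------------------------- PI3K / PLC
    par("k_pi3k_on", 2e-3, group="binding")
    par("k_pi3k_off", 0.1, group="dissociation")
    rxn("r_gab_pi3k", {"Ap": 1, "I": 1}, {"Ap.I": 1},
        "mass_action_reversible", ["k_pi3k_on", "k_pi3k_off"])
    par("kcat_pi3k", 1.0, group="other")
    par("km_pi3k", 200.0, role="michaelis_constant", opt=False)
    rxn("r_pip2_pip3", {"PIP2": 1}, {"PIP3": 1},
        "michaelis_menten", ["kcat_pi3k", "km_pi3k"], modifiers=["Ap.I"])
    par("kdp_pip3", 0.5, group="dephosphorylation", mut=True)
    rxn("r_pip3_pip2", {"PIP3": 1}, {"PIP2": 1},
        "mass_action_irreversible", ["kdp_pip3"])
    par("kcat_plc", 0.5, group="other")
    par("km_plc", 200.0, role="michaelis_constant", opt=False)
    rxn("r_pip2_ip3", {"PIP2": 1}, {"IP3": 1},
        "michaelis_menten", ["kcat_plc", "km_plc"], modifiers=["Pp"])
    par("k_ip3_rec", 0.5, group="other")
    rxn("r_ip3_rec", {"IP3": 1}, {"PIP2": 1},
        "mass_action_irreversible", ["k_ip3_rec"])

    # ----------------------------------------------------------------- observables
    _add_sigma_observables(net, mapk=mapk)

    net.validate()
    if mapk and endo:
        _assert_partition(net)
    return net


def _add_sigma_observables(net, mapk=True):
    """Sigma-state observables: every species containing the target molecule
    in the target modification state, weighted by copy number."""

    def sigma(name, base, mods):
        members, weights = [], []
        for sid, spc in net.species.items():
            if sid.endswith("_deg"):
                continue
            n = spc.count(base, mods)
            if n:
                members.append(sid)
                weights.append(float(n))
        net.add_observable(Observable(name, tuple(members), tuple(weights)))

    sigma("pEGFR_total", "Er", {"p"})
    sigma("pShc", "S", {"p"})
    sigma("pPlcg1", "P", {"p"})
    sigma("pShp2", "H", {"p"})
    sigma("pCbl", "C", {"p"})
    sigma("pHrs", "Hr", {"p"})
    sigma("EGFR_total", "Er", None)
    if mapk:
        sigma("pERK1", "ERK", {"pt", "pt2"})


def _assert_partition(net):
    """The canonical parameter bookkeeping of the full network."""
    opt = net.parameter_subset(wt_optimized=True)
    mut = net.parameter_subset(mutant_variable=True)
    fixed = net.parameter_subset(wt_optimized=False)
    counts = (len(opt), len(mut), len(fixed), len(net.parameters))
    if counts != (102, 54, 16, 118):
        raise NetworkValidationError(
            f"parameter partition broken: (opt, mutant, fixed, total) = {counts}, "
            "expected (102, 54, 16, 118)"
        )
    by_group = {
        "abundance": 12, "binding": 9, "dissociation": 9,
        "phosphorylation": 5, "dephosphorylation": 14,
        "internalization": 1, "ubiquitination": 1, "deubiquitination": 1,
        "degradation": 2,
    }
    for g, n in by_group.items():
        got = len([p for p in mut if net.parameters[p].group == g])
        if got != n:
            raise NetworkValidationError(
                f"mutant-variable group {g!r}: {got} parameters, expected {n}"
            )


def observable_for_protein(protein: str) -> str:
    try:
        return PROTEIN_OBSERVABLE[protein]
    except KeyError:
        raise KeyError(f"no observable mapped for protein {protein!r}") from None
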