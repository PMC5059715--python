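"""A reduced model of the NhaA pH-activation machinery, plus reference data.

NhaA, the *E. coli* sodium-proton antiporter, is activated when cytoplasmic pH
rises above ~6.5.  The reduced model collects the players of that activation
into an Ising-like system of coupled two-state degrees of freedom:

* the **pH sensor** — eight titratable residues at the cytoplasmic funnel
  entrance (Asp11, Glu78, Glu82, Glu252, His243, His253, His256, Lys249) plus
  two arginines (Arg81, Arg250) held permanently charged, whose collective net
  charge switches sign near the activation pH;
* the **core** — Asp133, Asp163, Asp164 and Lys300, with a salt-bridge
  coupling between Asp163 and Lys300;
* a **sodium-binding term** (``Na_core``) favoured by charged core aspartates
  and disfavoured by a charged Lys300 (bound sodium displaces the lysine and
  destabilizes its protonated state);
* two **conformational flags**: ``gate_open`` (the hydrophobic cytoplasmic
  gate, favoured by a charged Asp164) and ``tmv_bent`` (bending of the helix
  carrying Asp163, favoured by a neutral Lys300 and by bound sodium).

Coupling constants are calibration outputs, not measured quantities: they are
tuned once, by exact enumeration, so that (i) the apparent pKa of Lys300 is
~11.6 without sodium bound and ~8.9 with sodium bound, (ii) gate opening
titrates together with Asp164 deprotonation, and (iii) the bent-helix flag
tracks Lys300 deprotonation.  Sensor-site energy offsets place each sensor
residue at its macroscopic apparent pKa from the reference table below.
"""

from __future__ import annotations

import math
from typing import Mapping

from .system import LN10, BindingTerm, ConformationFlag, CoupledSystem, TitratableSite

#: Model-compound (solution) reference pKa's used for all sites.
MODEL_PKA = {"Asp": 4.0, "Glu": 4.4, "His": 6.5, "Lys": 10.4}

#: Macroscopic apparent-pKa table for the NhaA pH sensor and active site
#: (values from replica-exchange constant-pH simulations of the transporter;
#: used as calibration targets and as the input of the independent-site
#: net-charge reconstruction).  kind: "acid" contributes 0/-1, "base" +1/0.
NHAA_PKA_TABLE: dict[str, tuple[float, str]] = {
    # pH sensor
    "Asp11": (2.6, "acid"),
    "Glu78": (3.1, "acid"),
    "Glu82": (3.3, "acid"),
    "Glu252": (2.6, "acid"),
    "His243": (6.8, "base"),
    "His253": (6.3, "base"),
    "His256": (6.9, "base"),
    "Lys249": (11.2, "base"),
    # active site
    "Asp133": (4.5, "acid"),
    "Asp163": (2.4, "acid"),
    "Asp164": (5.0, "acid"),
    "Lys300": (10.1, "base"),
}

#: Residues of the pH sensor proper (the Fig-2-style net-charge set includes
#: the two fixed arginines below).
PH_SENSOR_SITES = (
    "Asp11", "Glu78", "Glu82", "Glu252", "His243", "His253", "His256", "Lys249",
)

#: Arginines held in the charged state (never titrated).
FIXED_ARGININES = {"Arg81": 1, "Arg250": 1}

#: pH ladders used by the replica-exchange runs the model emulates.
PH_LADDERS: dict[str, tuple[float, ...]] = {
    "run1": (
        1.5, 2.0, 2.5, 2.75, 3.0, 3.25, 3.5, 3.75, 4.0, 4.25, 4.5, 4.75,
        5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0, 8.5, 9.0, 9.5, 10.0, 10.25,
        10.5, 10.75, 11.0, 11.5,
    ),
    "run2-3": (
        2.5, 2.75, 3.0, 3.25, 3.5, 3.75, 4.0, 4.25, 4.5, 4.75, 5.0, 5.5,
        6.0, 6.5, 6.75, 7.0, 7.25, 7.5, 8.0, 8.5, 9.0, 9.5, 10.0, 10.25,
        10.5, 10.75, 11.0, 11.5,
    ),
}

# ----------------------------------------------------------- default tuning
# Salt-bridge coupling Asp163-Lys300 (kT per unit charge product): attractive
# when both are charged; its magnitude sets the upshift of the unbound Lys300
# apparent pKa above the model value.
J_SALT_BRIDGE = 2.76

# Sodium-binding term: intrinsic cost plus charge couplings (kT).
NA_MU = 1.0
NA_COUPLINGS = {"Asp163": 3.0, "Asp164": 2.0, "Lys300": 5.76459}

# Conformational flags (kT).
GATE_EPS = 1.5
GATE_SITE_COUPLINGS = {"Asp164": 2.5}
TMV_EPS = 0.5
TMV_SITE_COUPLINGS = {"Lys300": 3.0}
TMV_BINDING_COUPLINGS = {"Na_core": -1.0}

# Per-site deprotonation offsets (kT) calibrated by enumeration; see module
# docstring.  Sensor sites: offset = ln10 * (target - model reference).
_CORE_DEPROT_ENERGY = {
    "Asp133": LN10 * (4.5 - MODEL_PKA["Asp"]),
    "Asp163": LN10 * -0.4,
    "Asp164": LN10 * 1.54414,
    "Lys300": LN10 * 0.19398,
}

_SENSOR_KIND = {"Asp": "acid", "Glu": "acid", "His": "base", "Lys": "base"}

_CONFIG_KEYS = {
    "uncoupled",
    "reference_pka",
    "deprot_energy",
    "couplings",
    "na_mu",
    "na_couplings",
    "gate_eps",
    "gate_couplings",
    "tmv_eps",
    "tmv_couplings",
    "tmv_binding_couplings",
}


def _restype(name: str) -> str:
    return name[:3]


def build_nhaa_toy_model(config: Mapping | None = None) -> CoupledSystem:
    """Build the default reduced NhaA system, optionally overridden.

    ``config`` keys (all optional):

    - ``uncoupled`` (bool): zero every coupling, offset, mu and eps, so each
      site titrates exactly at its model-compound reference pKa;
    - ``reference_pka`` / ``deprot_energy``: per-site overrides (pH units / kT);
    - ``couplings``: mapping ``"A,B" -> J`` replacing default pair couplings;
    - ``na_mu`` / ``na_couplings``; ``gate_eps`` / ``gate_couplings``;
      ``tmv_eps`` / ``tmv_couplings`` / ``tmv_binding_couplings``.

    Unknown keys raise ``ValueError`` listing them.
    """
    cfg = dict(config or {})
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; valid: {sorted(_CONFIG_KEYS)}")
    uncoupled = bool(cfg.pop("uncoupled", False))
    ref_over = dict(cfg.get("reference_pka", {}))
    dg_over = dict(cfg.get("deprot_energy", {}))

    sites = []
    for name in PH_SENSOR_SITES + ("Asp133", "Asp163", "Asp164", "Lys300"):
        rtype = _restype(name)
        kind = _SENSOR_KIND[rtype]
        ref = ref_over.get(name, MODEL_PKA[rtype])
        if uncoupled:
            dg = 0.0
        elif name in dg_over:
            dg = dg_over[name]
        elif name in _CORE_DEPROT_ENERGY:
            dg = _CORE_DEPROT_ENERGY[name]
        else:
            # sensor site: land at the tabulated macroscopic pKa
            dg = LN10 * (NHAA_PKA_TABLE[name][0] - MODEL_PKA[rtype])
        sites.append(TitratableSite(name, kind, ref, deprot_energy=dg))

    if uncoupled:
        couplings: dict[tuple[str, str], float] = {}
        binding = [BindingTerm("Na_core", 0.0, {})]
        flags = [ConformationFlag("gate_open", 0.0), ConformationFlag("tmv_bent", 0.0)]
    else:
        if "couplings" in cfg:
            couplings = {tuple(k.split(",")): v for k, v in cfg["couplings"].items()}
        else:
            couplings = {("Asp163", "Lys300"): J_SALT_BRIDGE}
        binding = [
            BindingTerm(
                "Na_core",
                mu=cfg.get("na_mu", NA_MU),
                site_couplings=dict(cfg.get("na_couplings", NA_COUPLINGS)),
            )
        ]
        flags = [
            ConformationFlag(
                "gate_open",
                eps=cfg.get("gate_eps", GATE_EPS),
                site_couplings=dict(cfg.get("gate_couplings", GATE_SITE_COUPLINGS)),
            ),
            ConformationFlag(
                "tmv_bent",
                eps=cfg.get("tmv_eps", TMV_EPS),
                site_couplings=dict(cfg.get("tmv_couplings", TMV_SITE_COUPLINGS)),
                binding_couplings=dict(cfg.get("tmv_binding_couplings", TMV_BINDING_COUPLINGS)),
            ),
        ]

    return CoupledSystem(
        sites=sites,
        couplings=couplings,
        binding_terms=binding,
        flags=flags,
        fixed_charges=dict(FIXED_ARGININES),
    )


def single_site_system(
    name: str = "Lys300",
    kind: str = "base",
    reference_pka: float = MODEL_PKA["Lys"],
) -> CoupledSystem:
    """One uncoupled titratable site — the model-compound control system."""
    return CoupledSystem(sites=[TitratableSite(name, kind, reference_pka)])
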