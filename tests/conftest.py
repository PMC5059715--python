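"""Shared fixtures: small reference systems and oracle helpers."""

import numpy as np
import pytest

from cphmc.system import (
    BindingTerm,
    ConformationFlag,
    CoupledSystem,
    MicroState,
    TitratableSite,
)


@pytest.fixture(scope="session")
def acid_base_pair() -> CoupledSystem:
    """Asp-Lys-like pair with an attractive salt-bridge coupling."""
    return CoupledSystem(
        sites=[
            TitratableSite("Asp", "acid", 4.0),
            TitratableSite("Lys", "base", 10.4),
        ],
        couplings={("Asp", "Lys"): 2.76},
    )


@pytest.fixture(scope="session")
def three_site_system() -> CoupledSystem:
    """Three coupled sites of mixed kind — the detailed-balance workhorse."""
    return CoupledSystem(
        sites=[
            TitratableSite("A", "acid", 5.0),
            TitratableSite("B", "base", 7.0),
            TitratableSite("C", "acid", 6.0),
        ],
        couplings={("A", "B"): 1.5, ("B", "C"): -0.8},
    )


@pytest.fixture(scope="session")
def full_featured_system() -> CoupledSystem:
    """Sites + binding term + flag + a fixed charge: exercises every energy
    term class in one enumerable system (5 binary degrees of freedom)."""
    return CoupledSystem(
        sites=[
            TitratableSite("Asp", "acid", 4.0, deprot_energy=-0.5),
            TitratableSite("Lys", "base", 10.4),
            TitratableSite("His", "base", 6.5),
        ],
        couplings={("Asp", "Lys"): 2.0, ("Arg", "Asp"): 1.0},
        binding_terms=[BindingTerm("Na", mu=0.5, site_couplings={"Asp": 2.0, "Lys": 3.0})],
        flags=[
            ConformationFlag(
                "open", eps=1.0, site_couplings={"Asp": 1.5}, binding_couplings={"Na": -0.7}
            )
        ],
        fixed_charges={"Arg": 1},
    )


@pytest.fixture(scope="session")
def toy_model() -> CoupledSystem:
    from cphmc.nhaa import build_nhaa_toy_model

    return build_nhaa_toy_model()


def hand_summed_energy(system: CoupledSystem, state: MicroState) -> float:
    """Independent term-by-term energy oracle, written against the model
    definition rather than the implementation: explicit loops over every
    coupling pair, binding term and flag."""
    charges = {}
    for site, d in zip(system.sites, state.deprotonated):
        if site.kind == "acid":
            charges[site.name] = -1.0 if d else 0.0
        else:
            charges[site.name] = 0.0 if d else 1.0
    for label, c in system.fixed_charges.items():
        charges[label] = float(c)

    total = 0.0
    for (a, b), j in system.couplings.items():
        total += j * charges[a] * charges[b]
    for term, occ in zip(system.binding_terms, state.occupied):
        if occ:
            total += term.mu
            for label, k in term.site_couplings.items():
                total += k * charges[label]
    occ_by_name = {t.name: o for t, o in zip(system.binding_terms, state.occupied)}
    for flag, act in zip(system.flags, state.active):
        if act:
            total += flag.eps
            for label, g in flag.site_couplings.items():
                total += g * charges[label]
            for bname, h in flag.binding_couplings.items():
                total += h * occ_by_name[bname]
    for site, d in zip(system.sites, state.deprotonated):
        if d:
            total += site.deprot_energy
    return total


def empirical_joint(bits: np.ndarray) -> np.ndarray:
    """Empirical distribution over joint bit patterns (MSB-first codes)."""
    n = bits.shape[1]
    codes = bits @ (2 ** np.arange(n - 1, -1, -1))
    return np.bincount(codes, minlength=2**n) / len(codes)


def exact_joint(system: CoupledSystem, ph: float) -> np.ndarray:
    """Exact joint distribution in the same MSB-first code order."""
    from cphmc.system import enumerate_states

    res = enumerate_states(system, ph)
    n = res.states.shape[1]
    codes = res.states @ (2 ** np.arange(n - 1, -1, -1))
    out = np.zeros(2**n)
    np.add.at(out, codes, res.probabilities)
    return out


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(p - q).sum())
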