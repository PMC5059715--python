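"""Reduced titratable-system model: sites, couplings, binding terms, flags.

A :class:`CoupledSystem` is an Ising-like reduced Hamiltonian over binary
degrees of freedom: a deprotonation bit per titratable site, an occupancy bit
per ion-binding term and an activity bit per conformational flag.  Energies
are in kT at a single fixed temperature.  pH never enters the energy itself;
it couples to the deprotonation bits only through the semi-grand chemical
potential ``ln10 * (pH - pKa_ref)`` used by the sampler and the exact
enumerator (:func:`enumerate_states`).

The energy of a microstate is

    E(x) = sum_{u<v} J_uv q_u q_v
         + sum_b occ_b (mu_b + sum_u K_bu q_u)
         + sum_c act_c (eps_c + sum_u g_cu q_u + sum_b h_cb occ_b)
         + sum_i d_i dG_i

where q_u is the instantaneous charge of charge centre u (titratable sites
and fixed charges alike; fixed centres may appear in J and in the binding /
flag couplings, contributing constant fields) and dG_i is an optional kT
offset applied to the deprotonated state of site i.  Adding dG to one site
shifts its apparent pKa by +dG/ln10, which is how default models are
calibrated without touching the model-compound reference pKa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

LN10 = math.log(10.0)

#: hard cap on binary degrees of freedom for exact enumeration
MAX_ENUM_BITS = 20


class DimensionMismatchError(ValueError):
    """State vector lengths do not match the system definition."""


@dataclass(frozen=True)
class TitratableSite:
    """A two-state titratable residue (macroscopic; no tautomers).

    ``kind`` is ``"acid"`` (charges 0 protonated / -1 deprotonated) or
    ``"base"`` (+1 / 0).  ``reference_pka`` is the model-compound pKa;
    ``deprot_energy`` is a kT offset added when the site is deprotonated,
    used to calibrate apparent pKa shifts (shift = +deprot_energy/ln10).
    """

    name: str
    kind: str
    reference_pka: float
    deprot_energy: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("acid", "base"):
            raise ValueError(f"site {self.name!r}: kind must be 'acid' or 'base', got {self.kind!r}")
        if not (0.0 < self.reference_pka < 14.0):
            raise ValueError(
                f"site {self.name!r}: reference_pka must lie in (0, 14), got {self.reference_pka}"
            )

    @property
    def charge_protonated(self) -> int:
        return 0 if self.kind == "acid" else 1

    @property
    def charge_deprotonated(self) -> int:
        return -1 if self.kind == "acid" else 0

    def charge(self, deprotonated: int) -> int:
        return self.charge_deprotonated if deprotonated else self.charge_protonated


@dataclass(frozen=True)
class BindingTerm:
    """An ion-binding site with intrinsic affinity ``mu`` (kT, negative =
    favourable) and charge couplings ``site_couplings`` (kT per unit
    charge x occupancy); keys may be titratable sites or fixed charges."""

    name: str
    mu: float
    site_couplings: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ConformationFlag:
    """A two-state conformational degree of freedom (e.g. gate open/closed).

    ``eps`` is the intrinsic active-minus-inactive free energy (kT);
    ``site_couplings`` add kT per unit charge while active and
    ``binding_couplings`` add kT per occupied binding term while active.
    """

    name: str
    eps: float
    site_couplings: Mapping[str, float] = field(default_factory=dict)
    binding_couplings: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class MicroState:
    """One configuration: a bit per site (1 = deprotonated), per binding term
    (1 = occupied) and per flag (1 = active)."""

    deprotonated: tuple[int, ...]
    occupied: tuple[int, ...] = ()
    active: tuple[int, ...] = ()

    def bits(self) -> np.ndarray:
        return np.array(self.deprotonated + self.occupied + self.active, dtype=np.int8)


class CoupledSystem:
    """Reduced Hamiltonian over titratable sites, binding terms and flags.

    Parameters
    ----------
    sites:
        Titratable sites; names must be unique.
    couplings:
        Pairwise charge-charge couplings, as a mapping from an unordered
        label pair (site or fixed-charge names) to J in kT per unit charge
        product.  Self-couplings are rejected; symmetry is by construction.
    binding_terms, flags:
        Ion-binding terms and conformational flags.
    fixed_charges:
        Labels carrying a constant integer charge (e.g. arginines held
        charged); they contribute to couplings and to net-charge bookkeeping
        but never titrate.
    """

    def __init__(
        self,
        sites: Sequence[TitratableSite],
        couplings: Mapping[tuple[str, str], float] | None = None,
        binding_terms: Sequence[BindingTerm] = (),
        flags: Sequence[ConformationFlag] = (),
        fixed_charges: Mapping[str, int] | None = None,
    ) -> None:
        self.sites = tuple(sites)
        self.binding_terms = tuple(binding_terms)
        self.flags = tuple(flags)
        self.fixed_charges = dict(fixed_charges or {})

        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise ValueError("site names must be unique")
        overlap = set(names) & set(self.fixed_charges)
        if overlap:
            raise ValueError(f"labels cannot be both titratable and fixed: {sorted(overlap)}")
        self._site_index = {n: i for i, n in enumerate(names)}
        labels = set(names) | set(self.fixed_charges)

        self.couplings: dict[tuple[str, str], float] = {}
        for (a, b), j in (couplings or {}).items():
            if a == b:
                raise ValueError(f"self-coupling on {a!r} (J diagonal must be zero)")
            for lab in (a, b):
                if lab not in labels:
                    raise ValueError(f"coupling references unknown label {lab!r}")
            if not math.isfinite(j):
                raise ValueError(f"coupling ({a},{b}) is not finite")
            key = (a, b) if a <= b else (b, a)
            if key in self.couplings:
                raise ValueError(f"duplicate coupling for pair {key}")
            self.couplings[key] = float(j)

        term_names = [b.name for b in self.binding_terms]
        flag_names = [f.name for f in self.flags]
        if len(set(term_names)) != len(term_names) or len(set(flag_names)) != len(flag_names):
            raise ValueError("binding term / flag names must be unique")
        for b in self.binding_terms:
            for lab in b.site_couplings:
                if lab not in labels:
                    raise ValueError(f"binding term {b.name!r} couples to unknown label {lab!r}")
        for f in self.flags:
            for lab in f.site_couplings:
                if lab not in labels:
                    raise ValueError(f"flag {f.name!r} couples to unknown label {lab!r}")
            for lab in f.binding_couplings:
                if lab not in term_names:
                    raise ValueError(f"flag {f.name!r} couples to unknown binding term {lab!r}")

        self._quadratic_cache: tuple[float, np.ndarray, np.ndarray] | None = None

    # ------------------------------------------------------------------ sizes
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_bits(self) -> int:
        return len(self.sites) + len(self.binding_terms) + len(self.flags)

    @property
    def site_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sites)

    @property
    def bit_labels(self) -> tuple[str, ...]:
        """Column labels for the full bit vector: ``site:``/``occ:``/``flag:``."""
        return tuple(
            [f"site:{s.name}" for s in self.sites]
            + [f"occ:{b.name}" for b in self.binding_terms]
            + [f"flag:{f.name}" for f in self.flags]
        )

    def site(self, name: str) -> TitratableSite:
        return self.sites[self._site_index[name]]

    def reference_pkas(self) -> np.ndarray:
        return np.array([s.reference_pka for s in self.sites])

    # ------------------------------------------------------- charge utilities
    def _charge_affine(self, label: str) -> tuple[float, float, int | None]:
        """Return (a, b, bit) with q = a + b * x_bit; fixed charges have b=0."""
        if label in self._site_index:
            i = self._site_index[label]
            s = self.sites[i]
            return float(s.charge_protonated), float(s.charge_deprotonated - s.charge_protonated), i
        return float(self.fixed_charges[label]), 0.0, None

    # -------------------------------------------------------- quadratic form
    def quadratic_form(self) -> tuple[float, np.ndarray, np.ndarray]:
        """Energy as ``E(x) = const + h.x + x^T Q x / 2`` over the full bit
        vector (sites, then binding terms, then flags); Q symmetric, zero
        diagonal.  Cached; used by the sampler and the enumerator."""
        if self._quadratic_cache is not None:
            return self._quadratic_cache
        n = self.n_bits
        ns, nb = self.n_sites, len(self.binding_terms)
        const = 0.0
        h = np.zeros(n)
        Q = np.zeros((n, n))

        for (la, lb), j in self.couplings.items():
            aa, ba, ia = self._charge_affine(la)
            ab, bb, ib = self._charge_affine(lb)
            const += j * aa * ab
            if ia is not None:
                h[ia] += j * ba * ab
            if ib is not None:
                h[ib] += j * aa * bb
            if ia is not None and ib is not None:
                Q[ia, ib] += j * ba * bb
                Q[ib, ia] += j * ba * bb

        for k, b in enumerate(self.binding_terms):
            kb = ns + k
            h[kb] += b.mu
            for lab, kcoef in b.site_couplings.items():
                a, bslope, i = self._charge_affine(lab)
                h[kb] += kcoef * a
                if i is not None:
                    Q[kb, i] += kcoef * bslope
                    Q[i, kb] += kcoef * bslope

        term_index = {b.name: ns + k for k, b in enumerate(self.binding_terms)}
        for k, f in enumerate(self.flags):
            kf = ns + nb + k
            h[kf] += f.eps
            for lab, g in f.site_couplings.items():
                a, bslope, i = self._charge_affine(lab)
                h[kf] += g * a
                if i is not None:
                    Q[kf, i] += g * bslope
                    Q[i, kf] += g * bslope
            for bname, hc in f.binding_couplings.items():
                kb = term_index[bname]
                Q[kf, kb] += hc
                Q[kb, kf] += hc

        for i, s in enumerate(self.sites):
            h[i] += s.deprot_energy

        self._quadratic_cache = (const, h, Q)
        return self._quadratic_cache

    # ---------------------------------------------------------------- energy
    def check_state(self, state: MicroState) -> None:
        if (
            len(state.deprotonated) != len(self.sites)
            or len(state.occupied) != len(self.binding_terms)
            or len(state.active) != len(self.flags)
        ):
            raise DimensionMismatchError(
                f"state lengths ({len(state.deprotonated)}, {len(state.occupied)}, "
                f"{len(state.active)}) do not match system "
                f"({len(self.sites)}, {len(self.binding_terms)}, {len(self.flags)})"
            )

    def energy(self, state: MicroState) -> float:
        """Microstate energy in kT by direct term-by-term summation.

        Independent of pH; the quadratic form is checked against this in the
        test suite.
        """
        self.check_state(state)
        q = {s.name: float(s.charge(d)) for s, d in zip(self.sites, state.deprotonated)}
        q.update({lab: float(c) for lab, c in self.fixed_charges.items()})

        e = 0.0
        for (la, lb), j in self.couplings.items():
            e += j * q[la] * q[lb]
        for occ, b in zip(state.occupied, self.binding_terms):
            if occ:
                e += b.mu + sum(k * q[lab] for lab, k in b.site_couplings.items())
        occ_map = {b.name: o for b, o in zip(self.binding_terms, state.occupied)}
        for act, f in zip(state.active, self.flags):
            if act:
                e += f.eps
                e += sum(g * q[lab] for lab, g in f.site_couplings.items())
                e += sum(hc * occ_map[bn] for bn, hc in f.binding_couplings.items())
        for d, s in zip(state.deprotonated, self.sites):
            if d:
                e += s.deprot_energy
        return e

    # -------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "sites": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "reference_pka": s.reference_pka,
                    "deprot_energy": s.deprot_energy,
                }
                for s in self.sites
            ],
            "couplings": [
                {"pair": list(pair), "J": j} for pair, j in sorted(self.couplings.items())
            ],
            "binding_terms": [
                {"name": b.name, "mu": b.mu, "site_couplings": dict(b.site_couplings)}
                for b in self.binding_terms
            ],
            "flags": [
                {
                    "name": f.name,
                    "eps": f.eps,
                    "site_couplings": dict(f.site_couplings),
                    "binding_couplings": dict(f.binding_couplings),
                }
                for f in self.flags
            ],
            "fixed_charges": dict(self.fixed_charges),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoupledSystem":
        return cls(
            sites=[TitratableSite(**s) for s in d.get("sites", [])],
            couplings={tuple(c["pair"]): c["J"] for c in d.get("couplings", [])},
            binding_terms=[BindingTerm(**b) for b in d.get("binding_terms", [])],
            flags=[ConformationFlag(**f) for f in d.get("flags", [])],
            fixed_charges=d.get("fixed_charges", {}),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CoupledSystem":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def system_energy(system: CoupledSystem, state: MicroState) -> float:
    """Energy (kT) of ``state`` in ``system``; see :meth:`CoupledSystem.energy`."""
    return system.energy(state)


@dataclass(frozen=True)
class EnumerationResult:
    """Exact Boltzmann/semi-grand statistics of a small system at one pH."""

    system: CoupledSystem
    ph: float
    states: np.ndarray        # (2^n, n_bits) int8
    probabilities: np.ndarray  # (2^n,)

    def marginal(self, label: str) -> float:
        """Exact P(bit = 1) for a bit label (``site:X``/``occ:X``/``flag:X``
        or a bare site name)."""
        labels = self.system.bit_labels
        if label in labels:
            k = labels.index(label)
        elif f"site:{label}" in labels:
            k = labels.index(f"site:{label}")
        else:
            raise KeyError(f"unknown bit label {label!r}; valid: {list(labels)}")
        return float(self.probabilities @ self.states[:, k])

    def site_marginals(self) -> dict[str, float]:
        """Exact deprotonated fraction per titratable site."""
        return {s.name: self.marginal(s.name) for s in self.system.sites}

    def conditional_marginal(self, label: str, given: str, value: int = 1) -> float:
        """Exact P(bit[label] = 1 | bit[given] = value)."""
        labels = list(self.system.bit_labels)
        k = labels.index(label if label in labels else f"site:{label}")
        g = labels.index(given if given in labels else f"occ:{given}")
        mask = self.states[:, g] == value
        w = self.probabilities[mask]
        if w.sum() <= 0:
            raise ValueError(f"condition {given}={value} has zero probability")
        return float((w @ self.states[mask, k]) / w.sum())


def enumerate_states(system: CoupledSystem, ph: float) -> EnumerationResult:
    """Exact probabilities of all microstates at a given pH.

    Weights are ``exp(-E(x) + ln10 * sum_i d_i (pH - pKa_ref,i))``, normalized
    over all ``2^n`` bit patterns.  Refuses systems with more than
    ``MAX_ENUM_BITS`` binary degrees of freedom.  Serves as the brute-force
    oracle for the Monte Carlo sampler.
    """
    n = system.n_bits
    if n > MAX_ENUM_BITS:
        raise ValueError(
            f"exact enumeration limited to {MAX_ENUM_BITS} binary degrees of freedom, "
            f"system has {n}"
        )
    const, h, Q = system.quadratic_form()
    # all 2^n bit patterns, most-significant bit first
    codes = np.arange(2**n, dtype=np.uint32)[:, None]
    states = ((codes >> np.arange(n - 1, -1, -1, dtype=np.uint32)) & 1).astype(np.int8)
    x = states.astype(float)
    energies = const + x @ h + 0.5 * np.einsum("ki,ij,kj->k", x, Q, x)
    mu = LN10 * (ph - system.reference_pkas())
    logw = -energies + x[:, : system.n_sites] @ mu
    logw -= logw.max()
    w = np.exp(logw)
    return EnumerationResult(system, ph, states, w / w.sum())


def apparent_pka(
    system: CoupledSystem,
    site: str,
    ph_grid: Iterable[float] = np.arange(0.0, 14.01, 0.25),
    condition: tuple[str, int] | None = None,
) -> float:
    """Apparent (half-titration) pKa of a site from exact enumeration.

    Finds the pH at which the (optionally conditional) deprotonated fraction
    crosses 1/2, by linear interpolation on ``ph_grid``.  Raises if the
    fraction never brackets 1/2 on the grid.
    """
    grid = np.asarray(list(ph_grid), dtype=float)
    fracs = []
    for ph in grid:
        res = enumerate_states(system, ph)
        if condition is None:
            fracs.append(res.marginal(site))
        else:
            fracs.append(res.conditional_marginal(site, condition[0], condition[1]))
    f = np.asarray(fracs)
    above = f >= 0.5
    if not above.any() or above.all():
        raise ValueError(f"deprotonated fraction of {site!r} does not cross 1/2 on the grid")
    k = int(np.argmax(above))
    if k == 0:
        return float(grid[0])
    f0, f1 = f[k - 1], f[k]
    return float(grid[k - 1] + (0.5 - f0) / (f1 - f0) * (grid[k] - grid[k - 1]))
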