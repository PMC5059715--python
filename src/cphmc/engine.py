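"""Constant-pH Metropolis Monte Carlo and pH replica exchange.

Sampling targets the semi-grand distribution

    P(x | pH) ∝ exp(-E(x)) * prod_i 10^{d_i (pH - pKa_ref,i)}

over the binary degrees of freedom of a :class:`~cphmc.system.CoupledSystem`.
Single-bit Metropolis flips: deprotonation of site k is accepted with
``min(1, exp(-dE + ln10 (pH - pKa_ref,k)))``, reprotonation with the
reciprocal exponent, occupancy/flag flips with ``min(1, exp(-dE))``.

One *sweep* attempts one flip per binary degree of freedom in randomized
order (move weights can re-weight the per-class attempt rates).  Replica
exchange swaps configurations between adjacent pH conditions with
probability ``min(1, 10^{(pH_i - pH_j)(D_j - D_i)})`` where D is the total
number of deprotonated sites; even/odd neighbour pairs alternate between
exchange steps.  Randomness comes from one master seed spawning independent
per-replica streams, so results are reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .system import LN10, CoupledSystem

__all__ = [
    "SamplerConfig",
    "ProtonationEnsemble",
    "run_fixed_ph",
    "run_ph_replica_exchange",
    "exchange_probability",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Sampling schedule.

    ``burn_in=None`` defaults to 20% of ``sweeps`` (only the tail of each
    run is analysed).  ``move_weights`` are relative attempt rates for the
    (protonation, occupancy, flag) move classes; with the default (1, 1, 1)
    every bit is attempted once per sweep.
    """

    ph_ladder: tuple[float, ...]
    sweeps: int = 2000
    exchange_interval: int = 10
    burn_in: int | None = None
    seed: int = 0
    move_weights: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        ladder = tuple(float(p) for p in self.ph_ladder)
        object.__setattr__(self, "ph_ladder", ladder)
        if len(ladder) >= 2 and not all(b > a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("ph_ladder must be strictly increasing")
        if self.sweeps < 1:
            raise ValueError("sweeps must be >= 1")
        bi = self.effective_burn_in
        if not (0 <= bi < self.sweeps):
            raise ValueError("need sweeps > burn_in >= 0")
        if self.exchange_interval < 1:
            raise ValueError("exchange_interval must be >= 1")
        if any(w < 0 for w in self.move_weights) or sum(self.move_weights) == 0:
            raise ValueError("move_weights must be non-negative with a positive sum")

    @property
    def effective_burn_in(self) -> int:
        return self.sweeps // 5 if self.burn_in is None else self.burn_in

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "ph_ladder": self.ph_ladder,
                "sweeps": self.sweeps,
                "exchange_interval": self.exchange_interval,
                "burn_in": self.effective_burn_in,
                "seed": self.seed,
                "move_weights": self.move_weights,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class _Kernel:
    """Metropolis single-bit-flip kernel with an incrementally updated local
    field f = h + Q x, so each flip costs O(n_bits)."""

    def __init__(self, system: CoupledSystem, ph: float, rng: np.random.Generator):
        self.system = system
        self.ph = ph
        self.rng = rng
        const, h, Q = system.quadratic_form()
        self.h = h
        self.Q = Q
        self.n = system.n_bits
        self.ns = system.n_sites
        self.x = np.zeros(self.n, dtype=np.int8)
        self.f = h.copy()
        # per-site chemical potential favouring deprotonation
        self.mu = LN10 * (ph - system.reference_pkas())
        self.template = np.arange(self.n)

    def set_move_weights(self, weights: tuple[int, int, int]) -> None:
        ws, wo, wf = weights
        nb = len(self.system.binding_terms)
        nf = len(self.system.flags)
        parts = (
            [i for i in range(self.ns) for _ in range(ws)]
            + [self.ns + i for i in range(nb) for _ in range(wo)]
            + [self.ns + nb + i for i in range(nf) for _ in range(wf)]
        )
        if not parts:
            raise ValueError("move weights leave no degrees of freedom to attempt")
        self.template = np.array(parts)

    def set_state(self, x: np.ndarray) -> None:
        self.x = x.astype(np.int8).copy()
        self.f = self.h + self.Q @ self.x

    def n_deprotonated(self) -> int:
        return int(self.x[: self.ns].sum())

    def sweep(self) -> None:
        order = self.rng.permutation(self.template)
        logu = np.log(self.rng.random(order.size))
        x, f, Q, mu, ns = self.x, self.f, self.Q, self.mu, self.ns
        for k, lu in zip(order, logu):
            sign = 1 - 2 * int(x[k])  # +1 if flipping 0->1
            dlog = -sign * f[k]
            if k < ns:
                dlog += sign * mu[k]
            if dlog >= 0.0 or lu < dlog:
                x[k] += sign
                if sign > 0:
                    f += Q[:, k]
                else:
                    f -= Q[:, k]


@dataclass
class ProtonationEnsemble:
    """Per-pH series of sampled microstates (post burn-in).

    ``data`` holds one row per recorded frame with columns ``pH``, ``sweep``
    and one column per bit (labels like ``site:Asp164``, ``occ:Na_core``,
    ``flag:gate_open``).  Exchange statistics are per adjacent ladder pair.
    """

    ph_values: tuple[float, ...]
    bit_labels: tuple[str, ...]
    data: pd.DataFrame
    seed: int
    config_hash: str = ""
    exchange_attempts: np.ndarray | None = None
    exchange_accepts: np.ndarray | None = None

    @property
    def site_columns(self) -> list[str]:
        return [c for c in self.bit_labels if c.startswith("site:")]

    def frames_at(self, ph: float) -> pd.DataFrame:
        return self.data[np.isclose(self.data["pH"], ph)]

    def marginal(self, label: str) -> pd.Series:
        """Mean of one bit per pH condition (e.g. deprotonated fraction)."""
        col = label if label in self.data.columns else f"site:{label}"
        if col not in self.data.columns:
            raise KeyError(f"unknown bit label {label!r}; valid: {list(self.bit_labels)}")
        return self.data.groupby("pH", sort=True)[col].mean()

    def exchange_acceptance(self) -> np.ndarray:
        """Observed acceptance ratio per adjacent pH pair (nan if never tried)."""
        if self.exchange_attempts is None:
            return np.array([])
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.exchange_attempts > 0,
                self.exchange_accepts / np.maximum(self.exchange_attempts, 1),
                np.nan,
            )

    # ------------------------------------------------------------- persistence
    def to_csv(self, path) -> None:
        """Write frames as CSV with a JSON metadata comment header."""
        meta = {
            "ph_values": list(self.ph_values),
            "bit_labels": list(self.bit_labels),
            "seed": self.seed,
            "config_hash": self.config_hash,
            "exchange_attempts": None
            if self.exchange_attempts is None
            else self.exchange_attempts.tolist(),
            "exchange_accepts": None
            if self.exchange_accepts is None
            else self.exchange_accepts.tolist(),
        }
        with open(path, "w") as fh:
            fh.write("# cphmc-ensemble " + json.dumps(meta) + "\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ProtonationEnsemble":
        with open(path) as fh:
            first = fh.readline()
            meta = {}
            if first.startswith("# cphmc-ensemble "):
                meta = json.loads(first[len("# cphmc-ensemble "):])
                data = pd.read_csv(fh)
            else:
                fh.seek(0)
                data = pd.read_csv(fh, comment="#")
        bit_labels = meta.get(
            "bit_labels", [c for c in data.columns if c not in ("pH", "sweep")]
        )
        return cls(
            ph_values=tuple(meta.get("ph_values", sorted(data["pH"].unique()))),
            bit_labels=tuple(bit_labels),
            data=data,
            seed=meta.get("seed", -1),
            config_hash=meta.get("config_hash", ""),
            exchange_attempts=None
            if meta.get("exchange_attempts") is None
            else np.asarray(meta["exchange_attempts"]),
            exchange_accepts=None
            if meta.get("exchange_accepts") is None
            else np.asarray(meta["exchange_accepts"]),
        )


def run_fixed_ph(
    system: CoupledSystem,
    ph: float,
    config: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample at a single fixed pH; returns the post-burn-in bit matrix
    of shape ``(sweeps - burn_in, n_bits)``."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    kern = _Kernel(system, ph, rng)
    kern.set_move_weights(config.move_weights)
    burn = config.effective_burn_in
    out = np.empty((config.sweeps - burn, system.n_bits), dtype=np.int8)
    for s in range(config.sweeps):
        kern.sweep()
        if s >= burn:
            out[s - burn] = kern.x
    return out


def exchange_probability(
    state_i: np.ndarray | Sequence[int],
    state_j: np.ndarray | Sequence[int],
    ph_i: float,
    ph_j: float,
    n_sites: int | None = None,
) -> float:
    """Metropolis probability of swapping the configurations of two replicas.

    ``min(1, 10^{(pH_i - pH_j)(D_j - D_i)})`` with D the number of
    deprotonated sites; ``n_sites`` restricts the count to the leading site
    bits when full bit vectors are passed.
    """
    xi = np.asarray(state_i)[: n_sites] if n_sites else np.asarray(state_i)
    xj = np.asarray(state_j)[: n_sites] if n_sites else np.asarray(state_j)
    if xi.shape != xj.shape:
        raise ValueError("states must belong to the same system")
    expo = (ph_i - ph_j) * (float(xj.sum()) - float(xi.sum()))
    return float(min(1.0, 10.0**expo))


def run_ph_replica_exchange(system: CoupledSystem, config: SamplerConfig) -> ProtonationEnsemble:
    """pH replica exchange over the ladder in ``config``.

    Each replica runs ``exchange_interval`` sweeps between exchange steps;
    at each step either the even or the odd set of adjacent pairs (strictly
    alternating) attempts configuration swaps.  Records per-pair attempt and
    acceptance counts; frames are stored per pH condition.
    """
    ladder = config.ph_ladder
    if len(ladder) < 2:
        raise ValueError("replica exchange needs a ladder of at least 2 pH values")
    n_rep = len(ladder)
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(n_rep + 1)
    swap_rng = np.random.default_rng(streams[-1])
    kernels = []
    for r in range(n_rep):
        k = _Kernel(system, ladder[r], np.random.default_rng(streams[r]))
        k.set_move_weights(config.move_weights)
        kernels.append(k)

    ns = system.n_sites
    burn = config.effective_burn_in
    n_keep = config.sweeps - burn
    frames = np.empty((n_rep, n_keep, system.n_bits), dtype=np.int8)
    attempts = np.zeros(n_rep - 1, dtype=np.int64)
    accepts = np.zeros(n_rep - 1, dtype=np.int64)

    sweep_count = 0
    parity = 0
    while sweep_count < config.sweeps:
        block = min(config.exchange_interval, config.sweeps - sweep_count)
        for _ in range(block):
            for r in range(n_rep):
                kernels[r].sweep()
            if sweep_count >= burn:
                for r in range(n_rep):
                    frames[r, sweep_count - burn] = kernels[r].x
            sweep_count += 1
        if sweep_count >= config.sweeps:
            break
        for i in range(parity, n_rep - 1, 2):
            attempts[i] += 1
            di = kernels[i].n_deprotonated()
            dj = kernels[i + 1].n_deprotonated()
            expo = (ladder[i] - ladder[i + 1]) * (dj - di)
            if expo >= 0.0 or swap_rng.random() < 10.0**expo:
                accepts[i] += 1
                xi = kernels[i].x.copy()
                kernels[i].set_state(kernels[i + 1].x)
                kernels[i + 1].set_state(xi)
        parity ^= 1

    rows = []
    sweeps_idx = np.arange(burn, config.sweeps)
    for r, ph in enumerate(ladder):
        df = pd.DataFrame(frames[r], columns=list(system.bit_labels))
        df.insert(0, "sweep", sweeps_idx)
        df.insert(0, "pH", ph)
        rows.append(df)
    data = pd.concat(rows, ignore_index=True)
    return ProtonationEnsemble(
        ph_values=ladder,
        bit_labels=system.bit_labels,
        data=data,
        seed=config.seed,
        config_hash=config.config_hash(),
        exchange_attempts=attempts,
        exchange_accepts=accepts,
    )


def fixed_ph_ensemble(system: CoupledSystem, config: SamplerConfig) -> ProtonationEnsemble:
    """Independent fixed-pH runs over the ladder (no exchange); same output
    layout as :func:`run_ph_replica_exchange`, useful as its statistical
    control."""
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(len(config.ph_ladder))
    burn = config.effective_burn_in
    rows = []
    for r, ph in enumerate(config.ph_ladder):
        bits = run_fixed_ph(system, ph, config, rng=np.random.default_rng(streams[r]))
        df = pd.DataFrame(bits, columns=list(system.bit_labels))
        df.insert(0, "sweep", np.arange(burn, config.sweeps))
        df.insert(0, "pH", ph)
        rows.append(df)
    return ProtonationEnsemble(
        ph_values=config.ph_ladder,
        bit_labels=system.bit_labels,
        data=pd.concat(rows, ignore_index=True),
        seed=config.seed,
        config_hash=config.config_hash(),
    )
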