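"""Langevin dynamics, contact-map collective variables, metadynamics and
parallel tempering for the coarse-grained models.

The collective variables are contact-map distances to a reference
structure: with the rational switching function

    s(r) = (1 − x**n) / (1 − x**m),   x = r / (γ_s · r0),

(default n = 6, m = 10, γ_s = 1.2; the removable singularity at x = 1 is
replaced by its analytic limit n/m) the CV is

    D(X, ref) = Σ_pairs (s_ij(X) − s_ij(ref))²,

zero at the reference and growing as native pairs of the reference break.
Two such CVs, D_closed and D_open, span the free-energy surface of an
open↔closed transition.

The integrator is BAOAB — symmetric splitting of deterministic drift and an
exact Ornstein–Uhlenbeck kick — whose stationary distribution for a harmonic
potential is the Boltzmann distribution at the requested temperature.  All
randomness flows from one root seed through per-replica child streams, so
identical seeds give bitwise-identical runs.

Units: kcal/mol, Å, K; time in internal units with bead mass 1 (the
coarse-grained kinetics are not calibrated to physical time, only the
sampled ensemble matters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from kinodyn.forcefield import CGTopology, energy_forces

__all__ = [
    "ContactMapDistance", "MetadBias", "ReplicaLadder", "PTMetaDResult",
    "langevin_run", "pt_exchange", "run_ptmetad", "write_hills",
    "read_hills", "KB",
]

KB = 0.0019872041  # kcal/(mol·K)


# ---------------------------------------------------------------------------
# collective variables
# ---------------------------------------------------------------------------

@dataclass
class ContactMapDistance:
    """Contact-map distance CV to one reference structure."""

    name: str
    i: np.ndarray
    j: np.ndarray
    r0: np.ndarray                  # native distances of the reference, Å
    n: int = 6
    m: int = 10
    gamma_s: float = 1.2
    s_ref: np.ndarray = field(default=None)  # switching values at reference

    def __post_init__(self):
        self.i = np.ascontiguousarray(self.i, dtype=np.int64)
        self.j = np.ascontiguousarray(self.j, dtype=np.int64)
        self.r0 = np.ascontiguousarray(self.r0, dtype=np.float64)
        if self.s_ref is None:
            # by construction r = r0 at the reference
            self.s_ref = self._switch(self.r0)[0]

    @classmethod
    def from_topology(cls, top: CGTopology, tag_r0: np.ndarray | None = None,
                      name: str = "D", **kw) -> "ContactMapDistance":
        return cls(name=name, i=top.contact_i.copy(), j=top.contact_j.copy(),
                   r0=top.contact_r0.copy() if tag_r0 is None else tag_r0,
                   **kw)

    @classmethod
    def from_contact_map(cls, cmap, name: str = "D",
                         **kw) -> "ContactMapDistance":
        return cls(name=name, i=cmap.i.copy(), j=cmap.j.copy(),
                   r0=cmap.r0.copy(), **kw)

    def _switch(self, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """s(r) and ds/dr, handling the removable singularity at x = 1."""
        x = r / (self.gamma_s * self.r0)
        xn = x ** self.n
        xm = x ** self.m
        denom = 1.0 - xm
        singular = np.abs(denom) < 1e-10
        safe = np.where(singular, 1.0, denom)
        s = np.where(singular, self.n / self.m, (1.0 - xn) / safe)
        # ds/dx = [-n x^(n-1) (1-x^m) + m x^(m-1) (1-x^n)] / (1-x^m)^2
        dsdx_reg = (-self.n * x ** (self.n - 1) * denom
                    + self.m * x ** (self.m - 1) * (1.0 - xn)) / safe ** 2
        dsdx_lim = self.n * (self.n - self.m) / (2.0 * self.m)
        dsdx = np.where(singular, dsdx_lim, dsdx_reg)
        return s, dsdx / (self.gamma_s * self.r0)

    def value(self, coords: np.ndarray) -> float:
        return self.value_grad(coords)[0]

    def value_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        from kinodyn import _kernels
        x = np.ascontiguousarray(
            np.asarray(coords, dtype=float).reshape(-1, 3))
        if _kernels.HAVE_NUMBA:
            value, grad = _kernels.cv_value_grad(
                x, self.i, self.j, self.r0, self.s_ref,
                float(self.n), float(self.m), self.gamma_s)
            return float(value), grad
        return self.value_grad_numpy(x)

    def value_grad_numpy(self, coords: np.ndarray
                         ) -> tuple[float, np.ndarray]:
        """Reference numpy implementation of :meth:`value_grad`."""
        x = np.asarray(coords, dtype=float).reshape(-1, 3)
        d = x[self.j] - x[self.i]
        r = np.linalg.norm(d, axis=1)
        s, dsdr = self._switch(r)
        ds = s - self.s_ref
        value = float((ds ** 2).sum())
        coef = 2.0 * ds * dsdr / r
        grad = np.zeros_like(x)
        np.add.at(grad, self.j, coef[:, None] * d)
        np.add.at(grad, self.i, -coef[:, None] * d)
        return value, grad


# ---------------------------------------------------------------------------
# metadynamics bias
# ---------------------------------------------------------------------------

class MetadBias:
    """History-dependent Gaussian bias on one or more CVs.

    Plain metadynamics by default; well-tempered height scaling when
    ``wt_gamma`` is set (then ``temperature`` must be given too).
    """

    def __init__(self, sigma, height: float, pace: int,
                 wt_gamma: float | None = None,
                 temperature: float | None = None):
        self.sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
        if (self.sigma <= 0).any() or height <= 0:
            raise ValueError("hill height and widths must be positive")
        if pace < 1:
            raise ValueError("deposition pace must be >= 1")
        if wt_gamma is not None:
            if wt_gamma <= 1:
                raise ValueError("well-tempered gamma must exceed 1")
            if temperature is None:
                raise ValueError("well-tempered bias needs a temperature")
        self.height = float(height)
        self.pace = int(pace)
        self.wt_gamma = wt_gamma
        self.temperature = temperature
        self.steps: list[int] = []
        self.centers: list[np.ndarray] = []
        self.heights: list[float] = []
        self._carr: np.ndarray | None = None
        self._harr: np.ndarray | None = None

    @property
    def n_hills(self) -> int:
        return len(self.centers)

    def _arrays(self):
        if self._carr is None:
            self._carr = (np.array(self.centers)
                          if self.centers else np.empty((0, len(self.sigma))))
            self._harr = np.array(self.heights)
        return self._carr, self._harr

    def deposit(self, cv_values, step: int) -> None:
        c = np.atleast_1d(np.asarray(cv_values, dtype=float))
        w = self.height
        if self.wt_gamma is not None:
            dT = (self.wt_gamma - 1.0) * self.temperature
            w *= np.exp(-self.energy(c) / (KB * dT))
        self.steps.append(int(step))
        self.centers.append(c.copy())
        self.heights.append(float(w))
        self._carr = None

    def energy(self, cv_values) -> float:
        return self.energy_grad(cv_values)[0]

    def energy_grad(self, cv_values) -> tuple[float, np.ndarray]:
        """Bias potential and its gradient with respect to the CVs."""
        from kinodyn import _kernels
        s = np.atleast_1d(np.asarray(cv_values, dtype=float))
        carr, harr = self._arrays()
        if len(carr) == 0:
            return 0.0, np.zeros_like(s)
        if _kernels.HAVE_NUMBA:
            energy, grad = _kernels.bias_energy_grad(
                np.ascontiguousarray(s), carr, self.sigma, harr)
            return float(energy), grad
        z = (s[None, :] - carr) / self.sigma[None, :]
        g = harr * np.exp(-0.5 * (z ** 2).sum(1))
        energy = float(g.sum())
        grad = -(g[:, None] * z / self.sigma[None, :]).sum(0)
        return energy, grad

    def scale(self) -> float:
        """Factor converting −bias to free energy (well-tempered only)."""
        if self.wt_gamma is None:
            return 1.0
        return self.wt_gamma / (self.wt_gamma - 1.0)


def write_hills(bias: MetadBias, path, cv_names) -> None:
    with open(Path(path), "w") as fh:
        fh.write("# step " + " ".join(cv_names)
                 + " " + " ".join(f"sigma_{n}" for n in cv_names)
                 + " height\n")
        for step, c, h in zip(bias.steps, bias.centers, bias.heights):
            fh.write(f"{step} " + " ".join(f"{float(v)!r}" for v in c)
                     + " " + " ".join(f"{float(v)!r}" for v in bias.sigma)
                     + f" {float(h)!r}\n")


def read_hills(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (centers, sigmas, heights) arrays from a hills file."""
    rows = [ln.split() for ln in Path(path).read_text().splitlines()
            if ln and not ln.startswith("#")]
    data = np.array([[float(v) for v in row] for row in rows])
    n_cv = (data.shape[1] - 2) // 2
    return (data[:, 1:1 + n_cv], data[:, 1 + n_cv:1 + 2 * n_cv],
            data[:, -1])


# ---------------------------------------------------------------------------
# Langevin dynamics (BAOAB)
# ---------------------------------------------------------------------------

def langevin_run(force_fn, x0, n_steps: int, dt: float, friction: float,
                 temperature: float, rng: np.random.Generator,
                 mass: float = 1.0, v0=None, sample_stride: int = 0,
                 hook=None):
    """Integrate ẍ = f/m − γẋ + noise with the BAOAB splitting.

    ``force_fn(x) -> (energy, force)`` with ``x`` of any shape.  ``hook``
    (if given) is called as ``hook(step, x, v)`` after every step and may
    mutate ``x``/``v`` in place (used for metadynamics deposition and
    replica exchange).  Returns a dict with final state and samples.
    """
    x = np.array(x0, dtype=float)
    v = np.zeros_like(x) if v0 is None else np.array(v0, dtype=float)
    kT = KB * temperature
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(kT / mass * (1.0 - c1 * c1))
    energy, f = force_fn(x)
    samples = []
    energies = []
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * f / mass
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(x.shape)
        x += 0.5 * dt * v
        energy, f = force_fn(x)
        v += 0.5 * dt * f / mass
        if not np.isfinite(x).all():
            raise FloatingPointError(
                f"coordinates diverged at step {step}")
        if hook is not None:
            hook(step, x, v)
        if sample_stride and step % sample_stride == 0:
            samples.append(x.copy())
            energies.append(energy)
    return {"x": x, "v": v, "samples": samples, "energies": energies}


def check_timestep(top: CGTopology, dt: float, mass: float = 1.0) -> None:
    """Refuse a timestep above the stability bound of the stiffest bond.

    The stiffest curvature is 2·K_b (E = K_b Δr²), giving angular frequency
    ω = sqrt(2 K_b / m); BAOAB is stable for dt·ω < 2, and we require
    dt·ω ≤ 0.7 for accurate sampling.
    """
    if len(top.bonds) == 0:
        return
    omega = np.sqrt(2.0 * float(top.bond_k.max()) / mass)
    if dt * omega > 0.7:
        raise ValueError(
            f"dt = {dt} too large for stiffest bond "
            f"(dt*omega = {dt * omega:.2f} > 0.7); "
            f"use dt <= {0.7 / omega:.4f}")


# ---------------------------------------------------------------------------
# parallel tempering
# ---------------------------------------------------------------------------

@dataclass
class ReplicaLadder:
    """Temperature ladder plus exchange bookkeeping."""

    temperatures: np.ndarray        # K, strictly ascending
    exchange_pace: int = 500
    attempts: np.ndarray = None     # per neighbour pair
    accepts: np.ndarray = None

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if (np.diff(self.temperatures) <= 0).any():
            raise ValueError("temperatures must be strictly increasing")
        n_pairs = max(len(self.temperatures) - 1, 0)
        if self.attempts is None:
            self.attempts = np.zeros(n_pairs, dtype=int)
        if self.accepts is None:
            self.accepts = np.zeros(n_pairs, dtype=int)

    @classmethod
    def geometric(cls, t_low: float, t_high: float, n: int,
                  exchange_pace: int = 500) -> "ReplicaLadder":
        return cls(np.geomspace(t_low, t_high, n),
                   exchange_pace=exchange_pace)

    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.attempts > 0,
                            self.accepts / np.maximum(self.attempts, 1),
                            np.nan)


def pt_exchange(u_i: float, u_j: float, vi_si: float, vi_sj: float,
                vj_sj: float, vj_si: float, beta_i: float, beta_j: float,
                rng: np.random.Generator) -> bool:
    """Metropolis swap decision for neighbouring biased replicas.

    Δ = (β_i − β_j)(U(x_j) − U(x_i))
        + β_i [V_i(s(x_i)) − V_i(s(x_j))] + β_j [V_j(s(x_j)) − V_j(s(x_i))]

    and the swap is accepted with probability min(1, e^Δ).  With equal
    temperatures and biases Δ = 0 and the acceptance is 1.
    """
    delta = ((beta_i - beta_j) * (u_j - u_i)
             + beta_i * (vi_si - vi_sj) + beta_j * (vj_sj - vj_si))
    if delta >= 0:
        return True
    return rng.random() < np.exp(delta)


@dataclass
class PTMetaDResult:
    temperatures: np.ndarray
    biases: list                    # MetadBias per replica
    cv_series: np.ndarray           # (n_replicas, n_samples, n_cv)
    cv_steps: np.ndarray
    ladder: ReplicaLadder
    final_coords: np.ndarray        # (n_replicas, N, 3)
    trajectories: list              # per replica list of (N, 3) frames
    cv_names: tuple
    seed: int


def run_ptmetad(top: CGTopology, cvs, x0: np.ndarray, n_steps: int,
                seed: int, temperatures=(300.0, 350.0, 408.0, 476.0),
                dt: float = 0.02, friction: float = 1.0, mass: float = 1.0,
                hill_height: float = 0.3, hill_sigma=0.4,
                hill_pace: int = 500, exchange_pace: int = 500,
                cv_stride: int = 50, traj_stride: int = 0,
                wt_gamma: float | None = None,
                cv_walls=None, wall_k: float = 2.0,
                out_dir=None) -> PTMetaDResult:
    """Parallel-tempering metadynamics on contact-map CVs.

    Replicas run interleaved in one process; every ``exchange_pace`` steps
    neighbouring pairs (alternating even/odd) attempt a Metropolis swap of
    configurations, with velocities rescaled by sqrt(T_j/T_i).  Each replica
    deposits hills into its own bias.  The lowest-temperature replica is the
    one whose bias reconstructs the free-energy surface.

    ``cv_walls`` (one upper bound per CV, or None entries) adds half-
    harmonic restraints ``wall_k · (s − s_max)²`` above the bound,
    confining sampling to the transition-relevant region instead of the
    vast fully-unfolded part of contact-map space.  Walls are identical
    for all replicas and are excluded from the exchange bias terms (they
    cancel in the swap criterion).

    Returns the in-memory result; when ``out_dir`` is given, hills files,
    CV series (TSV) and run metadata are also written.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    check_timestep(top, dt, mass)
    temps = np.asarray(temperatures, dtype=float)
    n_rep = len(temps)
    ladder = ReplicaLadder(temps, exchange_pace=exchange_pace)
    betas = 1.0 / (KB * temps)
    root = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in root.spawn(n_rep + 1)]
    swap_rng = streams[-1]

    sigma = np.broadcast_to(np.atleast_1d(hill_sigma),
                            (len(cvs),)).astype(float)
    biases = [MetadBias(sigma, hill_height, hill_pace, wt_gamma=wt_gamma,
                        temperature=temps[r] if wt_gamma else None)
              for r in range(n_rep)]

    x = np.array([np.array(x0, dtype=float) for _ in range(n_rep)])
    v = np.zeros_like(x)
    kT = KB * temps
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(kT / mass * (1.0 - c1 * c1))

    walls = list(cv_walls) if cv_walls is not None else [None] * len(cvs)
    if len(walls) != len(cvs):
        raise ValueError("cv_walls must give one bound (or None) per CV")

    def step_forces(r, coords):
        rep, f = energy_forces(top, coords)
        vals = np.empty(len(cvs))
        grads = []
        for ic, cv in enumerate(cvs):
            val, gcv = cv.value_grad(coords)
            vals[ic] = val
            grads.append(gcv)
        _, dvds = biases[r].energy_grad(vals)
        for ic in range(len(cvs)):
            coef = dvds[ic]
            if walls[ic] is not None and vals[ic] > walls[ic]:
                coef += 2.0 * wall_k * (vals[ic] - walls[ic])
            if coef != 0.0:
                f -= coef * grads[ic]
        return rep.total, f, vals

    forces = np.empty_like(x)
    energies = np.empty(n_rep)
    cv_vals = np.empty((n_rep, len(cvs)))
    for r in range(n_rep):
        energies[r], forces[r], cv_vals[r] = step_forces(r, x[r])

    n_samp = n_steps // cv_stride if cv_stride else 0
    cv_series = np.empty((n_rep, n_samp, len(cvs)))
    cv_steps = np.empty(n_samp, dtype=int)
    trajectories: list[list[np.ndarray]] = [[] for _ in range(n_rep)]
    isamp = 0
    swap_parity = 0

    for step in range(1, n_steps + 1):
        for r in range(n_rep):
            rng = streams[r]
            v[r] += 0.5 * dt * forces[r] / mass
            x[r] += 0.5 * dt * v[r]
            v[r] = c1 * v[r] + c2[r] * rng.standard_normal(x[r].shape)
            x[r] += 0.5 * dt * v[r]
            energies[r], forces[r], cv_vals[r] = step_forces(r, x[r])
            v[r] += 0.5 * dt * forces[r] / mass
            if not np.isfinite(x[r]).all():
                raise FloatingPointError(
                    f"replica {r} diverged at step {step}")

        if step % hill_pace == 0:
            for r in range(n_rep):
                biases[r].deposit(cv_vals[r], step)

        if exchange_pace and step % exchange_pace == 0 and n_rep > 1:
            for p in range(swap_parity, n_rep - 1, 2):
                i, j = p, p + 1
                vi_si = biases[i].energy(cv_vals[i])
                vi_sj = biases[i].energy(cv_vals[j])
                vj_sj = biases[j].energy(cv_vals[j])
                vj_si = biases[j].energy(cv_vals[i])
                ladder.attempts[p] += 1
                if pt_exchange(energies[i], energies[j], vi_si, vi_sj,
                               vj_sj, vj_si, betas[i], betas[j], swap_rng):
                    ladder.accepts[p] += 1
                    scale = np.sqrt(temps[i] / temps[j])
                    x[[i, j]] = x[[j, i]]
                    v[[i, j]] = v[[j, i]] * np.array(
                        [scale, 1.0 / scale])[:, None, None]
                    for r in (i, j):
                        energies[r], forces[r], cv_vals[r] = \
                            step_forces(r, x[r])
            swap_parity = 1 - swap_parity

        if cv_stride and step % cv_stride == 0:
            cv_series[:, isamp] = cv_vals
            cv_steps[isamp] = step
            isamp += 1
        if traj_stride and step % traj_stride == 0:
            for r in range(n_rep):
                trajectories[r].append(x[r].copy())

    result = PTMetaDResult(
        temperatures=temps, biases=biases, cv_series=cv_series,
        cv_steps=cv_steps, ladder=ladder, final_coords=x,
        trajectories=trajectories,
        cv_names=tuple(cv.name for cv in cvs), seed=seed)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PTMetaDResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    names = list(result.cv_names)
    for r, bias in enumerate(result.biases):
        write_hills(bias, out_dir / f"hills.replica{r}.txt", names)
    header = "step\t" + "\t".join(names)
    for r in range(len(result.temperatures)):
        rows = np.column_stack([result.cv_steps,
                                result.cv_series[r]])
        np.savetxt(out_dir / f"cv.replica{r}.tsv", rows,
                   header=header, delimiter="\t", comments="")
    meta = {
        "seed": int(result.seed),
        "temperatures": result.temperatures.tolist(),
        "exchange_attempts": result.ladder.attempts.tolist(),
        "exchange_accepts": result.ladder.accepts.tolist(),
        "cv_names": names,
    }
    (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
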