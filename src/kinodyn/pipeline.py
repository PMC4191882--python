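"""End-to-end studies combining the analysis arms.

This module holds the canonical "study protocols" — parameter sets plus
orchestration — that the command-line interface, the test suite and the
reproduction script all share, so every entry point runs the same
computation:

* :func:`enm_study` — elastic-network modes, flexibility and the
  regulatory-domain coupling profile for one structure;
* :func:`two_state_study` — hybrid dual-basin build → parallel-tempering
  metadynamics → free-energy surface → open/closed basin report for a
  closed/open reference pair;
* :func:`paired_two_state_study` — the same transition with and without a
  rigid clamp docked over the open face, the package's scaled analog of
  comparing a kinase domain alone and with its activating partner domain.

The two-state defaults are the package's study conditions for the
synthetic chain: contact ε = 0.8 kcal/mol with softened toy dihedrals
(K_d1 = 0.3, K_d3 = 0.15), a 250/340 K replica pair, 0.5 kcal/mol hills of
width 0.5 every 200 steps, CV walls 4 units beyond the opposite reference
and 4·10⁵ steps per run.  docs/methods.md discusses how they were chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kinodyn.structure import Structure, compute_contact_map
from kinodyn.enm import (
    build_network, normal_modes, mode_fluctuations, coupling_matrix,
    coupling_to_region,
)
from kinodyn.forcefield import build_hybrid, CGTopology
from kinodyn.sampler import ContactMapDistance, run_ptmetad, PTMetaDResult
from kinodyn.fes import fes_from_hills, basin_report, BasinReport, FESGrid

__all__ = [
    "TwoStateProtocol", "TwoStateResult", "enm_study", "two_state_study",
    "paired_two_state_study",
]


def enm_study(structure: Structure, regions: dict,
              coupling_region: str = "SH2", cutoff: float = 10.0,
              gamma: float = 1.0, n_modes: int = 20,
              mode_range: tuple[int, int] = (0, 20)) -> dict:
    """Normal modes, mode-1 flexibility and coupling-to-region profile.

    ``regions`` maps region names to residue-number sets;
    ``coupling_region`` names the one whose allosteric coupling to the rest
    of the structure is profiled (e.g. the SH2 domain).
    """
    network = build_network(structure, cutoff=cutoff, gamma=gamma)
    modes = normal_modes(network, n_modes=max(n_modes, mode_range[1]))
    flex = mode_fluctuations(modes, (0, 1))
    coupling = coupling_matrix(modes, mode_range)
    if coupling_region not in regions:
        raise KeyError(
            f"region {coupling_region!r} not in region annotation "
            f"(have {sorted(regions)})")
    profile = coupling_to_region(coupling, regions[coupling_region])
    return {
        "network": network,
        "modes": modes,
        "mode1_flexibility": flex,
        "coupling": coupling,
        "profile": profile,
    }


@dataclass
class TwoStateProtocol:
    """Sampling parameters for the open↔closed free-energy calculation."""

    epsilon: float = 0.8             # contact depth, kcal/mol
    kd1: float = 0.3                 # toy-chain dihedral constants
    kd3: float = 0.15
    mixing_weight: float = 1.0
    closed_only_eps_scale: float = 1.0   # >1 deepens the closed basin
    temperatures: tuple = (250.0, 340.0)
    n_steps: int = 400_000
    dt: float = 0.02
    friction: float = 1.0
    hill_height: float = 0.5         # kcal/mol
    hill_sigma: float = 0.5          # CV units
    hill_pace: int = 200
    exchange_pace: int = 500
    wall_margin: float = 4.0         # wall = D(other reference) + margin
    wall_k: float = 2.0
    grid_bins: int = 64
    average_tail: float = 0.4
    extra_build: dict = field(default_factory=dict)


@dataclass
class TwoStateResult:
    topology: CGTopology
    cvs: tuple
    ptmetad: PTMetaDResult
    fes: FESGrid
    report: BasinReport
    ref_closed: tuple                # (D_closed, D_open) of the closed ref
    ref_open: tuple


def two_state_study(closed: Structure, open_: Structure,
                    switch_region: set, seed: int,
                    protocol: TwoStateProtocol | None = None,
                    out_dir=None, strict_report: bool = True
                    ) -> TwoStateResult:
    """Hybrid build → PT-metaD → FES → basin report for one system.

    With ``strict_report=False`` an unconverged surface (basins missing or
    never connecting) yields ``report=None`` instead of an exception —
    useful for exploratory short runs.
    """
    p = protocol or TwoStateProtocol()
    top = build_hybrid(closed, open_, switch_region,
                       epsilon=p.epsilon, mixing_weight=p.mixing_weight,
                       kd1=p.kd1, kd3=p.kd3, **p.extra_build)
    if p.closed_only_eps_scale != 1.0:
        top.contact_eps = np.where(top.contact_tag == "closed-only",
                                   top.contact_eps
                                   * p.closed_only_eps_scale,
                                   top.contact_eps)
    d_closed = ContactMapDistance.from_contact_map(
        compute_contact_map(closed), name="D_closed")
    d_open = ContactMapDistance.from_contact_map(
        compute_contact_map(open_), name="D_open")
    dc_at_open = d_closed.value(open_.xyz)
    do_at_closed = d_open.value(closed.xyz)

    result = run_ptmetad(
        top, [d_closed, d_open], closed.xyz, n_steps=p.n_steps, seed=seed,
        temperatures=p.temperatures, dt=p.dt, friction=p.friction,
        hill_height=p.hill_height, hill_sigma=p.hill_sigma,
        hill_pace=p.hill_pace, exchange_pace=p.exchange_pace,
        cv_stride=100,
        cv_walls=(dc_at_open + p.wall_margin, do_at_closed + p.wall_margin),
        wall_k=p.wall_k, out_dir=out_dir)

    temperature = p.temperatures[0]
    fes = fes_from_hills(result.biases[0], grid_bins=p.grid_bins,
                         names=("D_closed", "D_open"),
                         temperature=temperature,
                         average_tail=p.average_tail)
    try:
        report = basin_report(fes, temperature=temperature,
                              ref_closed=(0.0, do_at_closed),
                              ref_open=(dc_at_open, 0.0))
    except ValueError:
        if strict_report:
            raise
        report = None
    return TwoStateResult(topology=top, cvs=(d_closed, d_open),
                          ptmetad=result, fes=fes, report=report,
                          ref_closed=(0.0, do_at_closed),
                          ref_open=(dc_at_open, 0.0))


def paired_two_state_study(seed: int,
                           protocol: TwoStateProtocol | None = None,
                           chain_kwargs: dict | None = None,
                           out_dir=None) -> dict:
    """Free-energy comparison of the synthetic two-state chain with and
    without the rigid clamp over the open face.

    Returns the two :class:`TwoStateResult` objects plus the headline
    differences: the clamp-induced shift of ΔG_O-C and the change of the
    closed→open activation barrier.
    """
    from kinodyn.synthetic import make_two_state_chain

    kw = dict(chain_kwargs or {})
    results = {}
    for label, clamp in (("free", False), ("clamped", True)):
        chain = make_two_state_chain(clamp=clamp, **kw)
        sub_dir = None if out_dir is None else f"{out_dir}/{label}"
        results[label] = two_state_study(
            chain.closed, chain.open, chain.switch_region, seed=seed,
            protocol=protocol, out_dir=sub_dir)
    free, clamped = results["free"].report, results["clamped"].report
    results["delta_g_shift"] = (clamped.delta_g_open_closed
                                - free.delta_g_open_closed)
    results["barrier_change_closed_to_open"] = (
        clamped.barrier_from_closed - free.barrier_from_closed)
    return results
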