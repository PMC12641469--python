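"""End-to-end workflows on the toy cycle system.

``run_toy_cycle`` computes all four legs of the thermodynamic cycle for
one seed — two absolute solvation legs (T1, T2) by solute-solvent
decoupling and the two relative legs (gas, aqueous) by the dual-topology
analog — and returns the assembled :class:`~nlfep.protocols.CycleLedger`.

Window lengths here are desk-scale: chained windows of a few hundred
steps with 20 % discard and stride-4 subsampling, three independent
repeats per leg, repeat standard deviation as the leg uncertainty.
"""

from __future__ import annotations

from nlfep.fixtures import FixtureRecipe, make_cycle_fixture
from nlfep.protocols import (CycleLedger, cycle_closure,
                             make_lambda_schedule, run_asfe,
                             run_rsfe_analog)
from nlfep.sampling import SamplerSettings
from nlfep.system import ThermoState

__all__ = ["run_toy_cycle", "toy_settings"]


def toy_settings(seed: int = 0, n_steps: int = 500, save_interval: int = 5,
                 temperature: float = 300.0) -> SamplerSettings:
    """Desk-scale sampler settings (1 fs BAOAB, friction 1/ps)."""
    return SamplerSettings(
        timestep=0.001, friction=1.0, n_steps=n_steps,
        save_interval=save_interval, seed=seed,
        thermo=ThermoState(temperature),
    )


#: Reduced 12-point schedule for the toy cycle: dense where the offset
#: grows fastest (small lambda), coarser towards the decoupled state.
CYCLE_LAMBDAS = (0.0, 1 / 19, 2 / 19, 3 / 19, 4 / 19, 5 / 19, 6 / 19,
                 8 / 19, 10 / 19, 13 / 19, 16 / 19, 1.0)


def run_toy_cycle(seed: int = 0, scheme: int = 2, n_repeats: int = 3,
                  lambdas=CYCLE_LAMBDAS, n_steps: int = 500,
                  save_interval: int = 5, n_equil_steps: int = 300,
                  config: dict | None = None) -> CycleLedger:
    """All four legs of the toy cycle for one seed; returns the ledger.

    The same solvent box (generated from ``seed``) serves both end
    states; repeats differ only in their sampling seeds.  ``config`` may
    override sampler settings (keys as in the CLI YAML).
    """
    config = config or {}
    samp = config.get("sampler", {})
    n_steps = samp.get("n_steps", n_steps)
    save_interval = samp.get("save_interval", save_interval)

    fx = make_cycle_fixture(seed, FixtureRecipe(seed=seed))
    settings = toy_settings(seed, n_steps, save_interval,
                            samp.get("temperature", 300.0))
    schedule = make_lambda_schedule(values=lambdas)
    repeat_seeds = [seed * 1000 + 17 * k for k in range(n_repeats)]

    dg_solv_t1 = run_asfe(
        fx.t1_solv, fx.t1_gas, fx.model, scheme, schedule, settings,
        n_repeats=n_repeats, seeds=repeat_seeds,
        restraints=fx.restraints_t1_solv,
        gas_restraints=fx.restraints_t1_gas,
        n_equil_steps=n_equil_steps,
    )
    dg_solv_t2 = run_asfe(
        fx.t2_solv, fx.t2_gas, fx.model, scheme, schedule, settings,
        n_repeats=n_repeats, seeds=[s + 7 for s in repeat_seeds],
        restraints=fx.restraints_t2_solv,
        gas_restraints=fx.restraints_t2_gas,
        n_equil_steps=n_equil_steps, verify_gas=False,
    )
    dg_gas = run_rsfe_analog(
        fx.t1_gas, fx.t2_gas, fx.model, schedule, settings,
        restraints=fx.core_restraints_gas, scheme=scheme,
        variant_restraint=fx.variant_restraint, n_repeats=n_repeats,
        seeds=[s + 13 for s in repeat_seeds], n_equil_steps=n_equil_steps,
    )
    dg_aq = run_rsfe_analog(
        fx.t1_solv, fx.t2_solv, fx.model, schedule, settings,
        restraints=fx.core_restraints_solv, scheme=scheme,
        variant_restraint=fx.variant_restraint, n_repeats=n_repeats,
        seeds=[s + 23 for s in repeat_seeds], n_equil_steps=n_equil_steps,
    )
    return cycle_closure(dg_solv_t1, dg_solv_t2, dg_gas, dg_aq)
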