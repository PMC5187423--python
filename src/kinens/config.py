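"""Package-wide defaults.

All fluxes are carried internally on the "uptake = 100" basis; conversion to
other bases happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Internal flux basis: substrate uptake is scaled to this value.
UPTAKE_BASIS: float = 100.0

#: Default substrate uptake bound (basis units).
GLUCOSE_UPTAKE: float = 100.0

#: Default oxygen uptake bound (basis units).
OXYGEN_UPTAKE: float = 200.0

#: Generic magnitude bound for unconstrained fluxes (basis units).
FLUX_BOUND: float = 1000.0

#: Cap on elementary-step reversibility, R <= 1 - R_DELTA.
R_DELTA: float = 1e-6

#: Floor applied to sampled enzyme-form fractions (then renormalized);
#: avoids near-infinite anchored rate constants.
FRACTION_FLOOR: float = 1e-4

#: Steady-state tolerance on ||dC/dt||_inf (normalized concentrations).
SS_TOL: float = 1e-9

#: Maximum integration horizon (normalized time units) before giving up.
MAX_HORIZON: float = 1e6

#: Objective penalty for non-converged steady states.
PENALTY: float = 1e6

#: Relative-error floor in the objective: |v_exp| is floored at
#: EPS_REL_FRACTION * UPTAKE_BASIS.
EPS_REL_FRACTION: float = 1e-3

#: Mass-balance tolerance for LP/QP solutions, ||S.v||_inf on basis-100 scale.
LP_MASS_TOL: float = 1e-8

#: Tolerance on the ratio-FVA test for full coupling to biomass.
COUPLING_TOL: float = 1e-9


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters (desk-scale defaults)."""

    population: int = 256
    generations: int = 60
    crossover_prob: float = 0.9
    mutation_prob: float = 0.05
    tournament_size: int = 4
    elitism: int = 1
    seed: int = 0
    penalty: float = PENALTY
    workers: int = 1  # single-process; flag kept for API compatibility

    def validate(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")
        if self.tournament_size < 1 or self.elitism < 0:
            raise ValueError("bad tournament/elitism settings")
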