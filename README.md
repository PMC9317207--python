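# caregame

A two-population evolutionary game between health care organizations and
elderly social care organizations, each choosing between *participation*
and *nonparticipation* in integrated care provision. The package implements
the payoff structure, the replicator dynamics, equilibrium and stability
analysis, basin-of-attraction area sensitivities, time integration, and a
set of preset sweep experiments, behind both a Python API and a CLI.

## Model

Eleven nonnegative scalars (benefits `U1,U2`, costs `P1,P2,C1,C2`, incomes
`R1,R2`, subsidies `S1,S2,S1p`) define a bimatrix game. The participation
shares `(x, y)` evolve by replicator dynamics

```
dx/dt = x(1-x)(y*a + b),    dy/dt = y(1-y)(x*c + d)
```

where `(a, b, c, d)` are four reduced coefficients that fully determine the
dynamics. The five candidate fixed points (the four corners plus an
interior saddle) are classified from the Jacobian determinant/trace signs.
In the bistable regime ("scenario 1") both `O(0,0)` and `C(1,1)` are
stable, and the area of the basin converging to bilateral cooperation —
`1 - (x* + y*)/2` — is the synergy metric whose parameter sensitivities
the `basin_sensitivity` module computes (closed-form and finite-difference
routes, cross-checked).

## CLI

Parameters are a flat YAML/JSON mapping of the 11 names (see
`examples/baseline.yaml`; unknown or missing keys are rejected).

```sh
caregame analyze -p examples/baseline.yaml --table          # equilibria, regime, scenario
caregame simulate -p examples/baseline.yaml --x0 0.6 --y0 0.95 --csv traj.csv
caregame sensitivity -p examples/baseline.yaml -o sens.csv  # basin-area sensitivities
caregame sweep -p examples/baseline.yaml --quantity U1 \
    --grid 0.85,0.90,0.95,1.00,1.05 --x0 0.5 --y0 0.5
caregame reproduce-figure 4a                                # bundled preset sweeps (2a..6b)
```

Preset ids: `2a 2b 3a 3b` sweep the initial condition, `4a` (U1), `4b`
(R1), `5ab` (P1), `5c` (C1), `6a` (S1), `6b` (S1p) sweep one parameter
over its reference grid with everything else fixed at the baseline.

## Notes

- Classification treats signs within `1e-12` of zero as indeterminate;
  the interior fixed point always has zero trace (non-hyperbolic) and is
  labelled a saddle only through its negative determinant.
- Convergence of a trajectory to a corner requires both proximity
  (`delta`, default `1e-4`) and a field norm below `delta**2`; convergence
  times are continuous replicator time (no discrete step count is defined).
- The P1 sensitivity row is flagged globally indeterminate even when its
  local derivative has a clear sign: its sign genuinely changes across the
  feasible region (see `tests/test_basin_sensitivity.py`).
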