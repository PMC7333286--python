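# funcan

Formalized functional-analysis case models as simulable ODE systems.

`funcan` turns a clinician-style case conceptualization — components,
typed relations, reinforcement/inhibition loops — into a coupled system of
ordinary differential equations, simulates in-silico interventions, and
checks the resulting trajectories against qualitative clinical signatures.
It ships a reference case model of a patient with panic disorder:

- a discriminant stimulus (`Sd`, heart racing) drives catastrophizing
  (`Rc`), which drives panic (`Re`);
- panic and avoidant coping (`Rb`) are coupled as prey and predator:
  panic feeds avoidance, avoidance relieves panic;
- avoidance is reinforced by its perceived `benefits` and inhibited by its
  accumulating `costs`;
- persistent avoidance blocks falsification, so the credibility of the
  catastrophic interpretation (`cred_cat`) grows and amplifies
  catastrophizing — the loop that maintains the disorder;
- an augmented variant adds the credibility of a competing functional
  interpretation (`cred_fun`), which inhibits catastrophizing and competes
  with `cred_cat`.

Three formalized interventions are bundled: **exposure** (avoidant coping
clamped to 0 from onset), **cognitive reappraisal** (a constant input from
onset builds `cred_fun`), and **cbt** (both simultaneously). The four
scenario definitions — `baseline`, `exposure`, `reappraisal`, `cbt` — live
as YAML configs under `src/funcan/configs/`.

## Layout

| module | contents |
| --- | --- |
| `funcan.system_spec` | declarative model (`ComponentDef`, `TermDef`, `ParameterSet`, `ForcingProfile`, `SystemSpec`), reference-model factory, validation, phenomena-guided calibration |
| `funcan.dynamics` | RHS compilation, adaptive RK 4(5) and fixed-step Euler integration, `Trajectory`, CSV contract |
| `funcan.interventions` | `InterventionPlan`, exposure/reappraisal transformations, scenario resolution |
| `funcan.phenomena` | trajectory feature extraction, per-scenario check suites, the documented sustained-panic limitation check |
| `funcan.io_cli` | config loading (fail-closed YAML), trajectory export, time-series and 3D phase-portrait plots, CLI |

The bundled parameter values are tagged `calibrated`: component levels are
deliberately unit-free, so there is no authoritative numeric
parameterization to transcribe. The defaults were calibrated against the
scenario phenomena (all check suites pass, the no-intervention system
settles to a stable amplified state, and the two solvers agree within
1e-3). `ParameterSet` tracks per-value provenance (`supplement`,
`calibrated`, `user`) so replacing them with transcribed values later is a
bookkeeping change, not a refactor.

## CLI

```sh
# simulate a scenario, export CSV + resolved config, render plots,
# run its qualitative checks (exit 1 if any fails)
funcan run --scenario exposure --out out/ --plot --checks

# simulate from a config file (any run's resolved_config.yaml reproduces
# the run bit-identically)
funcan run --config out/resolved_config.yaml --out out2/

# validate a config/spec without simulating
funcan validate --config src/funcan/configs/cbt.yaml

# seeded random-search calibration against the baseline phenomena
funcan calibrate --ranges ranges.yaml --budget 200 --seed 0 --out params.yaml
```

Outputs per run: `trajectory.csv` (10 significant digits, one row per
output time), `resolved_config.yaml` (every default made explicit),
`checks.json`, and with `--plot` a time-series figure plus a 3D phase
portrait of panic x avoidant coping x catastrophic credibility (white
square marks the start of the trajectory, black square the end).

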