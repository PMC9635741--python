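"""Generate a random, structurally valid model and round-trip it.

The synthetic generator emits a severity-ordered progression model with
a Gompertz life table and two treatment archetypes (one-off cell-therapy
arm, per-cycle drug arm).  Every generated set passes validation, can be
written to the YAML/CSV configuration dialect, read back identically,
and run through the full pipeline.
"""

import tempfile
from pathlib import Path

from dkdcea import (
    classify_dominance,
    comparison_table,
    evaluate_arms,
    generate_parameter_set,
    generate_psa_specs,
    load_config,
    save_config,
    validate,
)

ps = generate_parameter_set(seed=42, n_ckd_states=2)
ps.psa_distributions = generate_psa_specs(ps, rel_se=0.1)
print("states:", ", ".join(ps.state_names))
print("violations:", validate(ps) or "none")

with tempfile.TemporaryDirectory() as tmp:
    path = str(Path(tmp) / "model.yaml")
    save_config(ps, path)
    back = load_config(path)
    print("round-trip identical:", back.states == ps.states
          and back.transitions == ps.transitions
          and back.settings == ps.settings)

rows = classify_dominance(evaluate_arms(ps), wtp=ps.settings.wtp)
print(comparison_table(rows).round(2).to_string(index=False))
print("\nGenerated arms land near cost-effectiveness indifference by design,"
      "\nso dominance patterns vary informatively across seeds.")
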