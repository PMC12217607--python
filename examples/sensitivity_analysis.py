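"""One-at-a-time sensitivity of cumulative emissions.

Perturbs the speed-of-adoption constants (halved/doubled), the cultured
meat/fish emission factor (x2/x3) and the caloric convergence target
(3515 instead of 3220 kcal) around the benchmark alternatives scenario."""

import foodshift as fs

fixture = fs.generate_fixture(seed=1)
spec = fs.ScenarioSpec(family="ALT_CE", fa=0.9, t_star=2025, composition="PB")

table = fs.sensitivity(fixture, spec)
base = table.loc["base", "cumulative_gt"]
print(f"{'perturbation':<16}{'cumulative (Gt)':>16}{'vs base':>10}")
for label, row in table.iterrows():
    print(f"{label:<16}{row.cumulative_gt:>16.1f}"
          f"{row.cumulative_gt - base:>+10.1f}")
# Adoption speed dominates: halving every alpha costs ~90 Gt, while even
# tripling the cultured emission factor adds only a few Gt under the
# mostly-plant-based composition.
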