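#!/usr/bin/env python
"""Derive the default LOH/background survivor rates for the screen simulator.

The targets are the observed mean non-LOH fractions among picked colonies:
~0.40 when the introduced variant abrogates mismatch repair and ~0.06 when
it does not.  With targeting efficiency ``e`` over ``n`` selected cells the
expected survivor counts are

    T = e * n            (targeted cells; survive only if abrogating)
    L = loh_rate * n     (loss-of-heterozygosity survivors)
    B = bg_rate  * n     (background survivors)

and the two targets give

    B / (B + L)         = 0.06        (neutral variant)
    (T + B) / (T+B+L)   = 0.40        (abrogating variant)

Solving: B = (0.06/0.94) L and L = T / (0.4/0.6 - 0.06/0.94).
The solved rates are stored in src/mmrscreen/data/defaults.yaml; this
script re-derives them and verifies the stored values.
"""

from importlib import resources

import yaml

TARGET_NONLOH_PATHOGENIC = 0.40
TARGET_NONLOH_NEUTRAL = 0.06
TARGETING_EFFICIENCY = 1e-3
N_CELLS = 1_500_000


def solve_rates() -> tuple[float, float]:
    t = TARGETING_EFFICIENCY * N_CELLS
    r = TARGET_NONLOH_NEUTRAL / (1 - TARGET_NONLOH_NEUTRAL)  # B = r * L
    denom = TARGET_NONLOH_PATHOGENIC / (1 - TARGET_NONLOH_PATHOGENIC) - r
    loh = t / denom
    bg = r * loh
    return loh / N_CELLS, bg / N_CELLS


def main() -> None:
    loh_rate, bg_rate = solve_rates()
    print(f"loh_survivor_rate        = {loh_rate:.5g}")
    print(f"background_survivor_rate = {bg_rate:.5g}")
    stored = yaml.safe_load(
        resources.files("mmrscreen").joinpath("data/defaults.yaml").read_text()
    )["screen"]
    for key, value in (
        ("loh_survivor_rate", loh_rate),
        ("background_survivor_rate", bg_rate),
    ):
        drift = abs(stored[key] - value) / value
        status = "OK" if drift < 5e-3 else "STALE"
        print(f"defaults.yaml {key} = {stored[key]:.5g} [{status}]")


if __name__ == "__main__":
    main()
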