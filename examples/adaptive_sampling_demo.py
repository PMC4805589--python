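"""Watch the adaptive SOA samplers at work.

Left: the roving distribution used for the second pair of a 2xSJ trial
concentrates near the observer's PSS as the session unfolds.  Right: the
Polya-urn TOJ sampler steers stimulus placement toward the region where
the order response flips.
"""

import numpy as np

from rovingsj import (ObserverParams, SyntheticObserver, draw_soa,
                      init_polya_urn, init_roving, polya_urn_update,
                      simulate_response, update_roving)

rng = np.random.default_rng(3)
observer = SyntheticObserver(params=ObserverParams.from_pss(40.0, sigma=40.0))

# --- roving 2xSJ distribution ------------------------------------------
state = init_roving()           # uniform over -60..+60 ms, 20-ms steps
constant_soas = np.arange(-300, 301, 20.0)
for trial in range(300):
    adapt = draw_soa(state, rng)
    const = float(rng.choice(constant_soas))
    first = bool(rng.random() < 0.5)
    pair = (adapt, const) if first else (const, adapt)
    choice = simulate_response(observer, "2xsj", pair, rng)
    state = update_roving(state, pair[0] if choice == 1 else pair[1])

mean_soa = float(np.sum(state.grid * state.weights))
top = sorted(float(g) for g in state.grid[np.argsort(state.weights)[-3:]])
print("roving distribution after 300 trials (observer PSS = +40 ms):")
print(f"  support {state.grid[0]:+.0f}..{state.grid[-1]:+.0f} ms, "
      f"mean {mean_soa:+.1f} ms, heaviest points {top}")

# --- Polya-urn TOJ sampler ---------------------------------------------
rng = np.random.default_rng(0)
urn = init_polya_urn(-140, 140, 20, k=8, hard_bound=300)
start_mean = float(np.sum(urn.grid * urn.weights))
for trial in range(400):
    soa = draw_soa(urn, rng)
    resp = simulate_response(observer, "toj", soa, rng)
    urn = polya_urn_update(urn, soa, resp)

urn_mean = float(np.sum(urn.grid * urn.weights))
print(f"urn after 400 TOJ trials: mean SOA {start_mean:+.1f} -> "
      f"{urn_mean:+.1f} ms (drifting toward the response flip at the PSS)")
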