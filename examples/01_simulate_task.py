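"""Generate one repeated-games Horizon Task session and inspect it.

Each session is a sequence of two-armed bandit games: Gaussian payoffs
(SD 8), one mean anchored at 40/60 and the other 4-20 points away, four
forced plays setting the [1 3] / [2 2] information condition, then 1 or 6
free choices.  Most games are duplicated: the second copy repeats the exact
forced sides and outcomes, at least 10 games later.
"""

import numpy as np

from dualnoise import TaskConfig, generate_session

config = TaskConfig()
games = generate_session(config, np.random.default_rng(0))

n_pairs = len({g.pair_id for g in games if g.pair_id})
print(f"session: {len(games)} games, {n_pairs} repeated pairs, "
      f"{sum(g.pair_id is None for g in games)} unpaired")

cells = {}
for g in games:
    cells[(g.horizon, g.info_condition)] = cells.get((g.horizon, g.info_condition), 0) + 1
print("games per horizon x information cell:", dict(sorted(cells.items())))

pair = [g for g in games if g.pair_id == "p0"]
print(f"\npair p0 appears at positions {[g.game_id for g in pair]}")
for g in pair:
    print(f"  game {g.game_id:3d}: horizon {g.horizon}, [{g.info_condition}], "
          f"means L/R = {g.mean_left:.0f}/{g.mean_right:.0f}, "
          f"forced {g.forced_sides} -> {g.forced_rewards}")
print("identical forced schedules and outcomes: the participant faces the "
      "same choice twice without knowing it.")
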