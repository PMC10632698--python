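"""Fit the solving-time predictor and walk through level decisions.

Pooled synthetic training data stands in for earlier participants. The best
regressor by training adjusted R-squared predicts the time t_p a player
should need at a level; measured times outside the band t_p +- c*sigma move
the player down or up one level.
"""

from puzzletrain import (
    build_ladder,
    decide_next_level,
    fit_time_model,
    generate_training_dataset,
    predict_time,
)
from puzzletrain.adaptive import level_sd
from puzzletrain.ladder import Game

attempts = generate_training_dataset(n_players=12, seed=11)
match3 = [a for a in attempts if a.game == Game.MATCH3]
model = fit_time_model(match3, seed=0)
print("candidate training adjusted R^2:")
for name, score in model.scores.items():
    marker = " <- selected" if name == model.selected else ""
    print(f"  {name:16s} {score:6.3f}{marker}")

ladder = build_ladder("match3")
level = ladder[8]
t_p = predict_time(model, level, {"session_index": 5, "running_mean_time": 90.0})
sigma = level_sd(match3, level)
print(f"\nlevel {level.index}: predicted time t_p = {t_p:.1f} s, "
      f"per-level sigma = {sigma:.1f} s, band half-width c*sigma = {0.5 * sigma:.1f} s")
for t_m in (t_p - sigma, t_p, t_p + sigma):
    decision = decide_next_level(t_m, t_p, sigma, c=0.5)
    label = {-1: "retreat", 0: "stay", 1: "advance"}[decision]
    print(f"  measured {t_m:6.1f} s -> decision {decision:+d} ({label})")
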