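"""Compute time-based performance indicators from a simulated session log.

Overall solving time (minutes), average target search time (s, match-3),
processing time per item (s) and the improvement slope (s/session; negative
means the player is getting faster).
"""

from puzzletrain import (
    AdaptiveService,
    InterventionSchedule,
    PlayerProfile,
    generate_training_dataset,
    simulate_intervention,
)
from puzzletrain.ladder import Game
from puzzletrain.metrics import summarize_performance
from puzzletrain.trial import reference_pretests

service = AdaptiveService(reference=reference_pretests())
service.train(generate_training_dataset(12, seed=11), seed=0)

profile = PlayerProfile("S01", skill=1.0, learning_rate=0.03, noise_sd=0.15, seed=4)
log = simulate_intervention(profile, InterventionSchedule(), service, seed=4)

for game in Game:
    summary = summarize_performance(log, profile.participant_id, game)
    print(f"{game.value}:")
    print(f"  overall solving time   {summary.overall_solving_time_min:7.1f} min")
    if game == Game.MATCH3:
        print(f"  avg target search time {summary.avg_target_search_time_s:7.2f} s")
    print(f"  time per item          {summary.processing_time_per_item_s:7.2f} s")
    print(f"  improvement slope      {summary.improvement_slope:+7.2f} s/session")
print("\na negative slope means per-session times shrink: in-game learning")
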