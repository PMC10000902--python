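"""Per-protein workload of the two workflows, from the shipped timing preset."""

from proteoformsim import hands_on_summary, load_timing_preset, per_entity_minutes, speed_ratio
from proteoformsim.workload import format_minutes

timings = load_timing_preset("du145-2023")
for name, t in timings.items():
    minutes = per_entity_minutes(t.total_hours, t.entities)
    hours, share = hands_on_summary(t)
    print(f"{name:8s} {t.total_hours:6.1f} h for {t.entities} entities "
          f"-> {format_minutes(minutes)} min/entity, {share:.0%} hands-on")

ratio, floored = speed_ratio(timings["dige"], timings["shotgun"])
print(f"\nshotgun is {ratio:.1f}x (at least {floored}x) faster per quantified+identified protein")
print("-> the gel workflow buys proteoform resolution with ~20x more time per")
print("   protein and far more bench work.")
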