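"""Run the whole analysis end to end on a synthetic 3-turtle cohort.

Simulation -> filtering -> state-space classification (with heuristic
fallback) -> period segmentation -> home ranges -> fidelity -> habitat
characterization -> threat overlay, printing the main summary tables.
"""

from internesting import McmcConfig, SimConfig, run_pipeline

res = run_pipeline(SimConfig(seed=3, n_turtles=3, n_steps=120),
                   McmcConfig(2, 800, 500, 5, seed=3))

print("== inter-nesting periods ==")
print(res.tables["periods"].to_string(index=False))
print("\n== cohort home-range summary (mean/SD by method) ==")
print(res.tables["cohort_summary"].round(1).to_string(index=False))
print("\n== movement and fidelity ==")
cols = ["period_id", "n_days", "tdm_km", "tdm_km_per_day", "fidelity_p", "fidelity"]
print(res.tables["movement"][cols].round(2).to_string(index=False))
print("\n== threat overlay (MCP centroids) ==")
print(res.tables["threats"].round(3).to_string(index=False))

# Every quantity a field study reports — period lengths, home-range areas,
# centroid depth and distance to shore, daily movement rates, fidelity
# classifications and platform/trawl-effort overlap — comes from one seeded,
# fully reproducible run.
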