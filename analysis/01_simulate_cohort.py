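"""Simulate the default study scenario and export its tables.

Generates a desk-scale cohort (n = 20 000) under the default scenario —
covariates calibrated to the study's baseline table, 1-5 dietary recalls
per participant, 20 cancer sites x 10 variants, baseline hazard calibrated
to 8.72% cumulative incidence over the 2006-2010 recruitment / 2022-05-31
censoring scheme — and writes the raw tables under results/cohort/.
"""

from pathlib import Path

from dietrisk import ScenarioConfig, run_scenario

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main():
    cfg = ScenarioConfig(n_participants=20_000, seed=20251001)
    res = run_scenario(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    res.raw.participants.to_csv(OUT / "cohort.tsv", sep="\t", index=False)
    res.raw.diet.to_csv(OUT / "diet_assessments.tsv", sep="\t", index=False)
    res.weights.to_csv(OUT / "weights.tsv", sep="\t", index=False)
    res.outcomes.to_csv(OUT / "outcomes.tsv", sep="\t", index=False)
    res.audit.to_frame().to_csv(OUT / "exclusion_audit.tsv", sep="\t", index=False)
    res.dataset.reset_index().to_csv(OUT / "analysis_dataset.tsv", sep="\t", index=False)

    print(f"simulated {res.raw.n} participants; {len(res.dataset)} in the analysis set")
    print(f"calibrated baseline hazard: {res.baseline_hazard:.3e} events/person-year")
    print(f"cumulative incidence: {res.incidence:.2%} "
          f"({int(res.dataset['event'].sum())} events)")
    print(f"median follow-up: {res.dataset['follow_up_years'].median():.2f} years")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
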