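"""Generate the synthetic study dataset.

Two smFRET trace conditions emulate a receptor whose active (low-FRET,
TM4-TM6 sensor) population is suppressed by a dimerizing modulator:
'apo' molecules carry a 26.5% active-state occupancy and 'modulator'
molecules 11.2%. Two immunogold point-pattern conditions emulate membrane
nanoclusters that grow under treatment (mean ~3 vs ~6 particles/cluster).
Everything is written under results/data/ with full ground truth.
"""

from pathlib import Path

from smfretglue import io as fio
from smfretglue.config import PatternConfig, SimulationConfig, stage_seed
from smfretglue.simulate import simulate_particle_pattern, simulate_traces

SEED = 2024
N_MOLECULES = 300
CONDITIONS = {"apo": 0.265, "modulator": 0.112}
# raw per-frame data is bulky; it lives under scratch/, the numbered
# drivers downstream read it from there and write only tables to results/
OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, active in CONDITIONS.items():
        cfg = SimulationConfig(
            seed=stage_seed(SEED, f"traces:{name}"),
            state_occupancies=(active, 1.0 - active),
        )
        traces, truth = simulate_traces(cfg, N_MOLECULES)
        fio.write_traces_csv(traces, OUT / f"traces_{name}.csv")
        fio.write_ground_truth(truth, OUT / f"truth_{name}.json")
        print(f"{name}: {len(traces)} molecules, true active fraction {active}")

    patterns = []
    for cond, mean_size in (("vehicle", 3.0), ("treated", 6.0)):
        for i in range(8):
            conf = PatternConfig(
                n_clusters=25, cluster_size_mean=mean_size,
                field_size=(30000.0, 30000.0), min_center_separation_factor=25.0,
                background_density=0.05,
            )
            pat, _ = simulate_particle_pattern(
                conf, seed=stage_seed(SEED, f"pattern:{cond}:{i}"),
                image_id=f"{cond}_{i}", condition_label=cond,
            )
            patterns.append(pat)
    fio.write_points_csv(patterns, OUT / "gold_particles.csv")
    print(f"gold particles: {sum(len(p.points) for p in patterns)} points, "
          f"{len(patterns)} images")


if __name__ == "__main__":
    main()
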