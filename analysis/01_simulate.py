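"""Generate the synthetic study: a planted-truth stand-in for the embryo
time course (oocyte, 4-cell, 8-cell, blastocyst), eight single blastomeres
with two latent lineage groups, ICM/TE reference profiles, a background
interactome with planted modules, gene panels and qPCR plates.

Writes everything as plain text under results/synthetic_study/.
"""

from pathlib import Path

import embryonet as en

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic_study"


def main(seed: int = 1) -> None:
    cfg = en.SyntheticConfig(seed=seed)
    truth = en.simulate_study(cfg, OUT)
    n_de = sum(len(v) for v in truth.de_genes_per_stage.values())
    print(f"synthetic study written to {OUT}")
    print(f"  genes: {cfg.n_genes}, stages: {list(cfg.stage_names)}, "
          f"replicates: {list(cfg.replicates_per_stage)}")
    print(f"  planted interactome modules: {len(truth.planted_modules)} "
          f"(sizes {[len(m) for m in truth.planted_modules]})")
    print(f"  stage-specific DE gene assignments: {n_de}")
    print(f"  blastomere groups: "
          f"{sorted(set(truth.blastomere_groups.values()))} over "
          f"{len(truth.blastomere_groups)} cells")


if __name__ == "__main__":
    main()
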