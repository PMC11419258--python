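"""Generate the synthetic study inputs with planted ground truth.

Writes the transcriptome count matrix (60 tumor / 20 control), the pooled
3-vs-3 proteome intensity matrix sharing the same planted DE genes, and the
drug annotation table into results/pipeline/.
"""

from revex.cli import stage_simulate
from revex.io import read_truth_table

from pipeline_config import RESULTS, config


def main() -> None:
    cfg = config()
    stage_simulate(cfg)
    truth = read_truth_table(RESULTS / "truth_genes.tsv")
    up = sum(v > 0 for v in truth.de_genes.values())
    down = len(truth.de_genes) - up
    print(f"wrote cohort to {RESULTS}")
    print(f"planted {len(truth.de_genes)} DE genes ({up} up, {down} down) "
          f"out of {cfg.sim.n_genes}")


if __name__ == "__main__":
    main()
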