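"""Per-layer differential expression at the study thresholds.

Transcripts: median-of-ratios normalization, Welch test on log2, BH-adjusted
p < 0.05 and |LFC| > 1. Proteins: log2 mean-intensity ratio, Welch test,
Bonferroni; one-group-only proteins are imputed to the maximum observed
|LFC| and kept when significant. Reports recovery against the planted truth.
"""

from pipeline_config import RESULTS, config
from revex.cli import stage_de
from revex.io import read_de_records, read_truth_table


def main() -> None:
    stage_de(config())
    truth = set(read_truth_table(RESULTS / "truth_genes.tsv").de_genes)
    for layer, path in (("rna", "de_rna.tsv"), ("protein", "de_protein.tsv")):
        recs = read_de_records(RESULTS / path)
        sig = {r.feature_id for r in recs if r.significant}
        imputed = sum(r.imputed_lfc for r in recs)
        sens = len(sig & truth) / len(truth)
        fdr = len(sig - truth) / max(len(sig), 1)
        extra = f", {imputed} imputed one-group-only LFCs" if layer == "protein" else ""
        print(f"{layer}: {len(sig)} significant of {len(recs)} tested "
              f"(sensitivity {sens:.2f}, FDR {fdr:.3f}{extra})")


if __name__ == "__main__":
    main()
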