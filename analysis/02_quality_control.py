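"""PCA-based sample QC on both omics layers.

Flags samples whose distance to their own group centroid in PC space exceeds
mean + 3 SD of within-group distances, and writes outlier-filtered matrices.
"""

from pipeline_config import RESULTS, config
from revex.cli import stage_qc


def main() -> None:
    stage_qc(config())
    lines = (RESULTS / "outliers.tsv").read_text().strip().splitlines()
    flagged = [l for l in lines if not l.startswith(("#", "layer"))]
    if flagged:
        print(f"flagged {len(flagged)} outlier sample(s):")
        for l in flagged:
            print("  " + l.replace("\t", " / "))
    else:
        print("no outlier samples flagged in either layer")


if __name__ == "__main__":
    main()
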