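"""Intersect the two DE layers into the disease expression profile.

Profile genes are significant in both transcriptome and proteome; each
carries its transcript-layer log2 fold change, sorted ascending.
"""

from pipeline_config import RESULTS, config
from revex.cli import stage_profile
from revex.io import read_profile, read_truth_table


def main() -> None:
    stage_profile(config())
    profile = read_profile(RESULTS / "profile.tsv")
    truth = set(read_truth_table(RESULTS / "truth_genes.tsv").de_genes)
    inside = len(set(profile.genes) & truth)
    up = sum(v > 0 for v in profile.entries.values())
    print(f"disease profile: {profile.n} genes ({up} up, {profile.n - up} down); "
          f"{inside} of {profile.n} are planted DE genes")


if __name__ == "__main__":
    main()
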