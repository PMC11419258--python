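"""Screen the perturbagen signature library against the disease profile.

Synthesizes the drug signature library from the built profile (so reversal
strength is a controlled ground truth), computes each signature's Pearson
concordance with the profile, keeps signatures with r < -0.2, and
median-aggregates passing signatures per drug.
"""

from pipeline_config import RESULTS, config
from revex.cli import stage_screen
from revex.io import read_concordances, read_truth_table


def main() -> None:
    stage_screen(config())
    results = read_concordances(RESULTS / "concordances.tsv")
    truth = read_truth_table(RESULTS / "truth_drugs.tsv")
    passed = [c for c in results if c.passed]
    passed_drugs = {c.perturbagen for c in passed}
    rev = set(truth.drugs_of("reverser"))
    mim = set(truth.drugs_of("mimicker"))
    print(f"screened {len(results)} signatures: {len(passed)} passed "
          f"(r < -0.2), covering {len(passed_drugs)} drugs")
    print(f"reverser recall {len(rev & passed_drugs)}/{len(rev)}, "
          f"mimickers passing {len(mim & passed_drugs)}/{len(mim)}")


if __name__ == "__main__":
    main()
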