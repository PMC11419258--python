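"""Cluster passing signatures, score drugs and rank candidates.

Ward/Minkowski clustering of the passing signatures (plus the profile as one
column), Regulation Score and Overall Coverage per drug, then ranking by RS
with the candidate filters: BBB >= 0.9, no prior disease trials, membership
in a reversal cluster.
"""

from pipeline_config import RESULTS, config
from revex.cli import stage_prioritize
from revex.io import read_scorecards, read_truth_table


def main() -> None:
    stage_prioritize(config())
    cards = read_scorecards(RESULTS / "scorecards.tsv")
    truth = read_truth_table(RESULTS / "truth_drugs.tsv")
    print(f"{len(cards)} drugs scored; top 5 by Regulation Score:")
    print("  rank drug       RS     OC     archetype      filters")
    for c in cards[:5]:
        label, alpha = truth.drug_archetypes[c.drug]
        tag = f"{label}" + (f"(a={alpha:.2f})" if alpha else "")
        print(f"  {c.rank:>4} {c.drug:<10} {c.rs:<6.3f} {c.oc:<6.3f} "
              f"{tag:<14} {'pass' if c.passes_filters else 'FAIL'}")
    n_pass = sum(c.passes_filters for c in cards)
    print(f"{n_pass} drugs pass all candidate filters")


if __name__ == "__main__":
    main()
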