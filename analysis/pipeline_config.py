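"""Shared study configuration for the numbered analysis scripts.

One seeded configuration drives the whole analysis: an imbalanced bulk
transcriptome cohort (60 tumor vs 20 control), a pooled 3-vs-3 proteome
sharing the same planted DE genes, and a 50-drug signature library with a
small minority of true reversers. All scripts write into ``results/pipeline``.
"""

from pathlib import Path

from revex.cli import PipelineConfig
from revex.synthetic_data import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "pipeline"

SEED = 1

SIM = SimConfig(
    n_genes=2000,
    n_case=60,
    n_control=20,
    frac_de=0.1,
    lfc_range=(1.5, 4.0),
    nb_dispersion=0.05,
    dropout_rate=0.2,
    n_drugs=50,
    sigs_per_drug=3,
    archetype_mix=(0.1, 0.1, 0.8),
    alpha_range=(0.6, 1.0),
    noise_sd=0.3,
    missing_rate=0.1,
    seed=SEED,
)


def config() -> PipelineConfig:
    return PipelineConfig(outdir=RESULTS, seed=SEED, sim=SIM,
                          proteome_n_case=3, proteome_n_control=3)
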