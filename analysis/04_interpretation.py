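"""Characterise the candidate list: hypergeometric term enrichment against a
synthetic annotation (one term seeded with the planted genes among random
ones) and degree-centrality hub ranking on a synthetic interaction network
with a planted hub.
"""
from pathlib import Path

import pandas as pd

from egwaskit import io as eio
from egwaskit.interpret import AnnotationSet, enrich, hub_rank
from egwaskit.synth import synthetic_annotation, synthetic_edges

DATA_DIR = Path("scratch/compendium")
RESULTS = Path("results/analysis")
SEED = 1


def main() -> None:
    universe = eio.read_universe(DATA_DIR / "universe.txt")
    truth = eio.read_truth(DATA_DIR / "truth.tsv", universe)
    ranking = pd.read_csv(RESULTS / "03_egwas_ranking.tsv", sep="\t", index_col=0)
    hits = set(ranking.index[ranking["significant"]])
    if not hits:
        hits = set(ranking.index[:25])

    ann = AnnotationSet(synthetic_annotation(universe, truth, seed=SEED))
    rows = enrich(hits, universe, ann)
    rows.to_csv(RESULTS / "04_enrichment.tsv", sep="\t", index=False,
                float_format="%.8g")
    print(rows.head(5).to_string(index=False))

    hub = sorted(truth.true_genes)[0]
    edges = synthetic_edges(sorted(truth.true_genes), hub=hub, seed=SEED)
    hubs = hub_rank(hits, edges)
    hubs.to_csv(RESULTS / "04_hubs.tsv", sep="\t", index=False)
    top = hubs.iloc[0]
    print(
        f"\ntop enriched term: {rows.loc[0, 'term']} "
        f"(k={rows.loc[0, 'k']}/{rows.loc[0, 'K']}, adj p={rows.loc[0, 'p_adjusted']:.3g}); "
        f"network hub: {top['gene_id']} (degree {top['degree']}, planted hub {hub})."
    )


if __name__ == "__main__":
    main()
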