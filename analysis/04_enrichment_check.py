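#!/usr/bin/env python
"""Hypergeometric enrichment of the up-regulated signature genes.

Queries the signature genes with r > 0 (up in RB1-positive samples)
against the planted up/down gene sets from step 01, over the universe of
all genes on the training matrix. By construction the up set should be
strongly enriched and the down set not at all — the synthetic analogue of
finding G1/S-phase genes condensed among the up-regulated signature.
Writes results/enrichment.tsv.
"""

from pathlib import Path

import pandas as pd

from rbratio import io as rio
from rbratio.enrichment import enrich, signature_query
from rbratio.signature import GeneStats, SignatureResult

DATA = Path("results/data")


def main() -> None:
    matrix = rio.read_expression_matrix(DATA / "training.matrix.tsv")
    sets = rio.read_gene_sets(DATA / "planted.gmt")
    sig_df = pd.read_csv("results/signature.tsv", sep="\t")
    sig = SignatureResult(
        tuple(GeneStats(r.gene_id, r.sd, r.r, r.p) for r in sig_df.itertuples()),
        sd_min=0.1, alpha=0.001, n_input_genes=matrix.shape[0],
    )

    query = signature_query(sig, "positive")
    report = enrich(query, sets, list(matrix.gene_ids))
    report.to_frame(bh=True).to_csv("results/enrichment.tsv", sep="\t", index=False)

    print(f"query: {len(query)} up-regulated signature genes "
          f"(universe {matrix.shape[0]} genes)")
    for r in report.results:
        print(f"  {r.set_name}: overlap {r.k}/{r.K}, p = {r.p:.3g}")


if __name__ == "__main__":
    main()
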