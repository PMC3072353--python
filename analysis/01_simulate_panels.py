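#!/usr/bin/env python
"""Generate the two synthetic study panels used by the downstream steps.

Writes, under results/data/:
  * training.matrix.tsv / training.labels.tsv — a 16 + 14 two-class
    log10-ratio expression panel with a 20-gene planted signature
    (CCND1 up and CDKN2A down in the RB1-positive class) over 200 null
    genes;
  * validation.ct.csv / validation.labels.tsv / validation.truth.tsv —
    a 7 + 5 qPCR panel with triplicate Ct wells per gene, class means of
    x = log10(CCND1/CDKN2A) at 1.2 (positive) and -0.4 (negative);
  * planted.gmt — the planted genes split into up/down sets, used by the
    enrichment check.
"""

from pathlib import Path

from rbratio import io as rio
from rbratio.simulate import SimulationConfig, simulate_ct_panel, simulate_expression_panel

SEED = 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)

    matrix, labels, truth = simulate_expression_panel(cfg)
    rio.write_expression_matrix(matrix, OUT / "training.matrix.tsv")
    rio.write_labels(labels, OUT / "training.labels.tsv")
    up = tuple(g for i, g in enumerate(truth) if i % 2 == 0)
    down = tuple(g for i, g in enumerate(truth) if i % 2 == 1)
    rio.write_gene_sets(
        rio.GeneSetCollection(
            (
                rio.GeneSet("planted_up", "planted genes up in RB1-positive", up),
                rio.GeneSet("planted_down", "planted genes down in RB1-positive", down),
            )
        ),
        OUT / "planted.gmt",
    )
    print(
        f"training panel: {matrix.shape[0]} genes x {matrix.shape[1]} samples "
        f"({labels.n_positive()} positive / {labels.n_negative()} negative), "
        f"{len(truth)} planted genes"
    )

    ct, ct_labels, truth_x = simulate_ct_panel(cfg.replace(n_pos=7, n_neg=5))
    rio.write_ct_table(ct, OUT / "validation.ct.csv")
    rio.write_labels(ct_labels, OUT / "validation.labels.tsv")
    with (OUT / "validation.truth.tsv").open("w") as fh:
        fh.write("sample_id\tx_true\n")
        for sid, x in truth_x.items():
            fh.write(f"{sid}\t{x!r}\n")
    print(
        f"validation panel: {len(ct)} Ct wells over {len(ct_labels)} samples "
        f"({ct_labels.n_positive()} positive / {ct_labels.n_negative()} negative)"
    )


if __name__ == "__main__":
    main()
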