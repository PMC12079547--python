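"""Generate the synthetic study compendium and write it as plain fixtures.

Writes the expression matrices, module catalog, gene annotations,
genotypes, methylation bins, TF prior edges, marker sets and the planted
truth to results/fixtures/ in the pipeline's standard dialects.
"""

import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "config", Path(__file__).with_name("00_config.py")
)
config = importlib.util.module_from_spec(spec)
spec.loader.exec_module(config)

from modnet import io_formats as io
from modnet.io_formats import ModuleCatalog
from modnet.synthetic import (
    simulate_compendium,
    simulate_gene_annotations,
    simulate_genotypes_and_effects,
    simulate_markers,
    simulate_regulatory_network,
)


def main() -> None:
    cfg = config.study_config()
    out = config.RESULTS / "fixtures"
    out.mkdir(parents=True, exist_ok=True)

    datasets, catalog, truth = simulate_compendium(cfg)
    anns = simulate_gene_annotations(cfg)
    genotypes, bins, truth = simulate_genotypes_and_effects(cfg, anns, datasets[0], truth)
    priors, tfs, truth = simulate_regulatory_network(cfg, catalog, truth)
    markers, truth = simulate_markers(cfg, catalog, truth)

    for ds in datasets[:2]:  # two cohorts on disk suffice for inspection
        io.write_expression(ds, out / f"expr_{ds.dataset_id}.tsv")
    io.write_gmt(catalog, out / "modules.gmt")
    io.write_bed(anns, out / "genes.bed")
    io.write_vcf(genotypes, out / "genotypes.vcf")
    io.write_methylation(bins, out / "meth_bins.bed", out / "meth_levels.tsv")
    io.write_edges(priors, out / "priors.tsv")
    (out / "tfs.txt").write_text("\n".join(tfs) + "\n")
    io.write_gmt(
        ModuleCatalog({ct: ("markers", g) for ct, g in markers.items()}, catalog.universe),
        out / "markers.gmt",
    )
    truth.to_json(out / "truth.json")

    print(f"compendium: {len(datasets)} datasets x {datasets[0].n_genes} genes "
          f"x {datasets[0].n_samples} samples")
    print(f"planted: {len(truth.gene_module_assoc)} gene-module associations, "
          f"{len(truth.module_module_assoc)} module couplings, "
          f"{len(truth.eqtl_truth)} eQTL effects, driver {sorted(truth.driver_truth)}")
    print(f"fixtures under {out}")


if __name__ == "__main__":
    main()
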