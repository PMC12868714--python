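"""Simulate a small dual-nuclease screen and write it to disk.

Builds an hgRNA library (exon deletions, gene knockouts, intergenic and
non-targeting controls), draws a hidden effect model, and emits guide-capture
and expression matrices with a ground-truth table.
"""

from pathlib import Path

from hgscreen import io as hio
from hgscreen.library import simulate_guide_library
from hgscreen.simulate import (default_marker_sets, simulate_cells,
                               simulate_truth)

outdir = Path("scratch/example_screen")

library = simulate_guide_library(n_exon_targets=4, guides_per_exon=3,
                                 n_gene_targets=2, guides_per_gene=2,
                                 n_intergenic=40, n_nontargeting=8, seed=1)
truth = simulate_truth(library, n_genes=1000, mean_affected_per_target=20,
                       lfc_scale=1.5, escape_fraction=0.1, seed=2)
s_markers, g2m_markers = default_marker_sets(truth)
guides, expr, cell_truth = simulate_cells(
    library, truth, n_cells_per_guide=50, p_detect_cas9=0.95,
    p_detect_cas12a=0.9, doublet_rate=0.05, decoupling_rate=0.02,
    s_markers=s_markers, g2m_markers=g2m_markers, seed=3)

hio.write_matrix_dir(guides, outdir / "guides")
hio.write_matrix_dir(expr, outdir / "expression")
library.write_tsv(outdir / "library.tsv")
cell_truth.to_csv(outdir / "cell_truth.tsv", sep="\t")

print(f"library: {len(library)} hgRNAs "
      f"({len(library.targets('exon_deletion'))} exon targets x 3 guides, "
      f"{len(library.targets('gene_knockout'))} knockouts x 2, "
      f"{len(library.targets('intergenic'))} intergenic, "
      f"{len(library.targets('non_targeting'))} non-targeting)")
print(f"cells: {expr.n_obs}, genes: {expr.n_vars}")
print(f"doublets: {cell_truth['is_doublet'].sum()}, "
      f"decoupled: {cell_truth['is_decoupled'].sum()}, "
      f"escaping: {cell_truth['is_escaping'].sum()}")
print(f"written to {outdir}/")
# The truth table is what downstream recovery is scored against: every cell's
# real hgRNA(s), doublet/decoupled/escaping status and cell-cycle phase.
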