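"""Cytometry-style fold-change statistics: geometric means, CIs, topologies.

Simulates ON (with trigger) and OFF (no trigger) cell populations with a
planted 9-fold geometric-mean difference at 2000 cells per arm, bins cells
by transfection-marker intensity at half-log intervals, and compares a
closed-loop against an open-loop sensor variant.
"""

from dartvadar import bin_by_marker, fold_change, topology_ratios
from dartvadar.fixture_sim import SimSpec, simulate_cells

cells = simulate_cells(SimSpec(seed=11, n_cells=2000, true_fold_change=9.0))
on = cells[cells.population == "on"].reporter.to_numpy()
off = cells[cells.population == "off"].reporter.to_numpy()

result = fold_change(on, off, n_boot=1000, seed=11)
print(f"fold change {result.fold_change:.2f} "
      f"(95% CI {result.ci95[0]:.2f}-{result.ci95[1]:.2f}, planted 9.0, "
      f"n = {result.n_on}/{result.n_off} cells)")

binned, excluded = bin_by_marker(cells.marker, log10_bin_width=0.5)
print(f"marker binning: {binned['bin'].nunique()} half-log bins, "
      f"{excluded} non-positive cells excluded")

# closed loop: same maximal activation, lower background -> higher dynamic range
cl_cells = simulate_cells(SimSpec(seed=12, n_cells=2000, true_fold_change=9.0,
                                  mean_log_off=3.0))
ol_cells = simulate_cells(SimSpec(seed=13, n_cells=2000, true_fold_change=3.0,
                                  mean_log_off=4.1))
cl = fold_change(cl_cells[cl_cells.population == "on"].reporter,
                 cl_cells[cl_cells.population == "off"].reporter, seed=12)
ol = fold_change(ol_cells[ol_cells.population == "on"].reporter,
                 ol_cells[ol_cells.population == "off"].reporter, seed=13)
ratios = topology_ratios(cl, ol)
print(f"log10 fold-change ratio CL/OL: {ratios['log10_fold_change_ratio']:+.2f} "
      f"(positive -> autocatalysis helps)")
print(f"log10 basal ratio CL/OL:       {ratios['log10_basal_ratio']:+.2f} "
      f"(negative -> lower background)")
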