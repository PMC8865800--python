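"""Choose the number of cell states with BIC.

Simulates data with 3 true states and scans k = 1..7; the BIC minimum
identifies the true cluster count because extra clusters buy likelihood
only at the cost of n_genes more rate parameters each.
"""

from primus import select_k, simulate_primus

data = simulate_primus(n_genes=80, n_cells=300, r=2, k=3, seed=5, separation=1.0)
scan = select_k(data.counts, data.design, k_range=range(1, 8), n_init=5, seed=2)

print(scan.table.to_string(index=False))
print(f"selected k = {scan.selected_k} (true k = 3)")
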