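# Example study: synthetic cohort with a central spatial preference.
# Run with:  nucleomap run --config examples/study.yaml
seed: 11
output: nucleomap_out
synthetic:
  n_nuclei: 20
  pattern:
    model: central          # csr | central | annular | shell_excluded
    n_points: [poisson, 8]  # fixed int, or [poisson, mean]
    params: {sigma_r: 0.3}
  imaging:
    shape: [20, 192, 192]   # (nz, ny, nx)
    spacing: [0.36, 0.15, 0.15]  # (z, y, x), micrometres
segmentation:
  threshold: otsu           # otsu | fixed:<v> | quantile:<q>
  min_size: 4
  connectivity: 26
landmarks:
  n_rings: 9
  n_per_ring: 16
grid:
  axis: 32                  # bounding-grid resolution for the mean shape
inference:
  M: 199                    # Monte-Carlo null replicates
  alpha: 0.05
  connectivity: 6
  statistic: cluster_mass   # cluster_mass | cluster_size | tfce
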