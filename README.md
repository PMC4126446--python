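# lobulesim

Agent-based simulation of chronic inflammation and fibrosis in a 2-D patch
of liver lobules, with a joint-constrained mechanical skeleton and a
non-perturbing virtual elastography read-out.

A tissue patch is a honeycomb of hexagonal lobules: portal-triad nodes at
the vertices, septa (paired boundary segments with prismatic joints, tied to
the triads by revolute joints) on the edges, and hepatocytes packed inside.
Pulses of centrilobular toxicity kill hepatocytes; Kupffer cells phagocytize
the debris, activate, and polarize from a pro-inflammatory M1 phenotype
(TNF secretion, bystander hepatocyte death) toward an anti-inflammatory,
pro-fibrotic M2 phenotype (TGF secretion). Uncleared dead cells release
HMGB1, which recruits monocytes as fresh activated Kupffer cells. Portal
fibroblasts and hepatic stellate cells transform into myofibroblasts that,
under TGF, proliferate and deposit collagen onto existing structure —
periportal fibrosis first, then bridging chains. Tissue stiffness is probed
by copying the mechanical state, shrinking cell diameters slightly, pinning
the outer boundary, applying an inward impulse to every internal node and
measuring their mean displacement one overdamped step later; the copy is
discarded, leaving the simulation bit-identical.

Built-in experiments: baseline injured runs (cell censuses, cytokine
totals, collagen growth, elastography series, aggregated as mean ± SD over
replicates) and two in silico therapies — anti-TNF (faster TNF degradation)
and M2 enhancement (increased Kupffer TGF production) — compared against
baseline with paired seeds.

## Command line

```bash
# run one scenario (per-replicate + aggregate CSVs, manifest)
lobulesim run --config cfg.yaml --seed 1 --replicates 10 --out results/

# baseline vs. both therapies with paired seeds + Markdown report
lobulesim compare --config cfg.yaml --replicates 10 --out results/

# score a saved state JSON with the virtual elastography probe
lobulesim elastography state.json

# emit a named test configuration (single_lobule | seven_lobule | paper_scale)
lobulesim fixture paper_scale --out paper.yaml

# render a saved state to PNG (collagen drawn blue)
lobulesim render state.json --out snapshot.png
```

Configuration is a YAML file with sections `geometry`, `hepatocyte`,
`kupffer`, `fibrogenic`, `dead_cell`, `field_tnf` / `field_tgf` /
`field_hmgb1`, `injury`, `therapy`, `mechanics` and `run`; omitted keys take
the calibrated defaults (`lobulesim fixture` writes fully expanded files).
The `paper_scale` fixture is the calibrated full patch: a 4×4 honeycomb
(hex side 9.7168, unit cell diameter) whose automated center-outward spiral
fill plus replication emerges at exactly 3,857 hepatocytes, from which the
initial Kupffer (964) and stellate cell (321) counts follow via the 60/15/5%
liver cell-type proportions.

## Package layout

| module | contents |
| --- | --- |
| `lobulesim.geometry`  | honeycomb skeleton, node classification, packing sites, spiral fill |
| `lobulesim.fields`    | cytokine grids: deposit, 5-point diffusion + decay, threshold queries |
| `lobulesim.agents`    | per-type agent state and behavioral rules |
| `lobulesim.mechanics` | collision resolution, prismatic/revolute joints, elastography |
| `lobulesim.engine`    | config schema, simulation state, step loop, scenarios, (de)serialization |
| `lobulesim.analysis`  | steady-state detection, peak ordering, scenario comparison |
| `lobulesim.io_cli`    | YAML config I/O, fixtures, PNG snapshots, run manifests |
| `lobulesim.cli`       | `lobulesim` command group |
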