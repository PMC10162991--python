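# carriermd

Analysis toolkit for studies of nucleotide regulation in mitochondrial
carriers (SLC25 family), combining the computational layers such studies
need: geometric analysis of protein–ligand MD trajectories, structural
metrics for membrane-embedded helix bundles, carrier-fold sequence
symmetry, and oxygraph respirometry quantification. It is aimed at
structural bioinformaticians and membrane-protein biophysicists who have
trajectories (or oxygraph traces) in hand and want reproducible,
threshold-explicit implementations of the standard observables.

Uncoupling protein 1 (UCP1) dissipates the mitochondrial proton gradient
as heat; purine nucleotides such as GDP inhibit it by binding in the
common substrate-binding site of the carrier fold. Characterising that
regulation computationally requires a specific set of measurements,
each of which this package implements with an explicit, tested
criterion:

* **Interaction detection** — a *contact* between two atom groups exists
  when any cross pair is closer than 3 Å (strict); a *hydrogen bond*
  when the donor–acceptor distance is below 3.3 Å and the
  donor–hydrogen–acceptor angle exceeds 140°; a *pi interaction* when at
  least three atoms of an aromatic protein ring lie within 3.8 Å of the
  nucleotide's ring atoms; a *salt bridge* is bonded while the pair
  shares at least one hydrogen bond. Per-frame flags are aggregated into
  contact-time tables (fraction of the analysis window, which excludes
  the first 200 ns by default; replica mean ± SEM) and salt-bridge
  bonded-time fractions.
* **Ligand position and orientation** — the signed vertical distance of
  the nucleotide's center of mass from the protein center (the mean of
  18 alpha carbons: the residue 27–29 triplets on odd helices and the
  83–85 triplets on even helices) and the cosine of the angle between
  the phosphate→base vector and the membrane normal.
* **Water permeability** — the membrane slab is split into three equal
  z-regions; a permeation event is a water oxygen traversing the three
  regions in order while staying within 15 Å of the protein, with
  periodic-boundary jumps discarded as false positives.
* **Helix splay** — the in-plane radius of gyration of the per-helix
  mean Cα positions in a running 12 Å window,
  `R_XY(z) = sqrt( (1/N) Σᵢ |rᵢ(z) − r̄(z)|² )`,
  profiling how far the bundle funnels open along the membrane normal.
* **Pose clustering** — frames are superposed on the transmembrane-helix
  Cα atoms (least-squares, no reflection); ligand poses are clustered by
  Ward-linkage agglomerative clustering refined by K-means seeded from
  the agglomerative centroids, reporting occupancies and a
  representative frame per cluster.
* **Triplet sequence mapping** — the carrier fold's three paralogous
  two-helix repeats are aligned and every column mapped to a residue
  *triplet*, named by one-letter codes plus the first-repeat number
  (e.g. RRR84, QNL85, FIW88), plus pairwise percent identity between
  aligned sequences.
* **Respirometry** — fluxes (−dO₂/dt) averaged in 1-minute windows after
  each injection reduce to the respiratory control ratio
  `RCR = F_ADP / F_oligomycin`, the activation fraction
  `(F_FA − F_NADH) / (F_CCCP − F_NADH)` and the nucleotide inhibition
  rate `1 − (F_nucleotide − F_NADH) / (F_FA − F_NADH)`, with boxplot
  replicate summaries (linear-interpolation quartiles, 1.5·IQR whiskers).

Because microsecond trajectories are not shippable, the package includes
first-class synthetic-data generators (`carriermd.synthetic_data`) that
plant known ground truth — scripted interaction schedules with ≥ 0.2 Å
margins against every threshold, scripted water crossings, closed-form
splay profiles, pose blobs with exact occupancies, piecewise-linear
oxygraph traces — so every stage is verifiable end to end without
downloads.

## Worked example

```python
from carriermd import (TraceSpec, generate_oxygraph_trace,
                       phase_mean_fluxes, respiration_metrics)

assay = generate_oxygraph_trace(TraceSpec(noise_sd=1.0, seed=4))
fluxes = phase_mean_fluxes(assay.trace, window=60.0)
act = respiration_metrics(fluxes, "activation").activation_fraction
inh = respiration_metrics(fluxes, "inhibition").inhibition_rate
print(f"activation {act:.3f}  inhibition {inh:.3f}")
```

prints

```
activation 0.500  inhibition 0.751
```

meaning lauric acid drove respiration to 50% of the CCCP-uncoupled
maximum (after removing the NADH baseline), and GDP suppressed 75% of
that fatty-acid-induced respiration — matching the generator's planted
fluxes (F_NADH = 10, F_LA = 30, F_GDP = 15, F_CCCP = 50) up to the added
noise. The `examples/` directory holds one short script per capability
(splay, permeation, contact tables, clustering, triplets, respirometry),
each printing its result next to the planted truth. A thin `carriermd`
command exposes the same operations from the shell
(`carriermd --help`).

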