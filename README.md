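# gen3d

Reconstruction of 3D models of individual chromosomes from
intra-chromosomal Hi-C contact data.

A contact list is binned into a per-chromosome interaction-frequency
matrix (centromere/gap regions removed, optional ICE or coverage
balancing). Candidate 3D structures — one point per 1 Mb region — are
scored by four percentage sub-scores:

* **CS** — contacts satisfied (squared inter-locus distance ≤ 7 μm²),
* **NS** — non-contacts satisfied (squared distance > 7 μm²),
* **IF** — contacts satisfied, weighted by interaction frequency,
* **MS** — chain-adjacent distances inside the [0.2, 20.25] μm² restraints,

combined as a weighted average (weights 2, 2, 3, 1). Starting from a
random conformation (chain growth for > 200 regions, a random unit
sphere otherwise), the model is refined by three stages:

1. **adaptation** — best-of-10 random suffix translations per locus, kept
   only on strict score improvement; improving iterations are snapshot
   into an ensemble;
2. **simulated annealing** — per-member Boltzmann-accepted proposals under
   geometric cooling, with a best-ever archive;
3. **genetic algorithm** — selection of the top-scoring half, single-point
   coordinate crossover, and 10,000 score-gated point mutations.

The highest-scoring member of the final ensemble is the model.

## CLI

```sh
# bin a contact list (chrom pos_a pos_b per line) into a matrix
gen3d matrix --pairs pairs.txt --chrom chr22 --resolution 1000000 \
             --gaps auto --normalize none --out chr22.tsv

# build a 3D model (PDB) and its score report
gen3d build --matrix chr22.tsv --out chr22.pdb --report chr22.json \
            --adapt-iters 50000 --sa-iters 50 --ga-mutations 10000 --seed 1

# score an existing model, dump the heat-map label matrix
gen3d score --model chr22.pdb --matrix chr22.tsv --labels-out labels.tsv

# synthetic fixture: ground-truth chain + implied contact matrix
gen3d simulate --n 30 --bond 1.5 --confine 6 --seed 1 \
               --out-truth truth.pdb --out-matrix matrix.tsv

# consistency protocols
gen3d validate converge --matrix matrix.tsv --seeds 1,2 --adapt-iters 2000
gen3d validate recover  --matrix matrix.tsv --seed 1 --adapt-iters 2000
```

Matrices are read/written as dense TSV (with `#` metadata headers),
sparse `i j count` triplets, or HDF5 (`.h5`/`.hdf5`).

## Layout

| module | role |
|---|---|
| `gen3d.hic_io` | contact-list parsing, binning, gap removal, normalization, matrix I/O |
| `gen3d.scoring` | CS/NS/IF/MS sub-scores, weighted total, satisfaction labels |
| `gen3d.init` | growth / random-sphere initial conformations |
| `gen3d.optimize` | adaptation, simulated annealing, genetic algorithm, pipeline |
| `gen3d.synthetic` | ground-truth generators for self-contained testing |
| `gen3d.report` | PDB I/O, heat maps, range-stratified CS, validation protocols |
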