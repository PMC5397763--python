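# interlock

Analysis toolkit for **autoinhibited two-domain protein complexes** — the
situation where a protein's own N-terminal domain docks onto its signalling
domain (e.g. a Toll/interleukin-1 receptor, TIR, domain) to keep the protein
silent until activation. Given two per-domain sequence alignments and a
structural ensemble of the docked complex, `interlock` answers three
questions a structural bioinformatician asks about such a complex:

1. **Which residue pairs co-evolve between the two domains?**
   Pseudocount-regularised mutual information on the concatenated alignment.
   For columns *i*, *j* the joint distribution is estimated as

       P_PP(x_i, y_j) = (1 − τ) P_obs(x_i, y_j) + τ q(x_i) q(y_j),
       τ = (1 + b) / (exp(a · Neff(i,j)) + b),

   where *q* are the column profiles and *Neff* the number of sequences
   ungapped at both columns. MI = Σ P log(P / P_x P_y) (nats) is then
   background-corrected with the average-product correction,
   MIp(i,j) = MI(i,j) − MI(i,·) MI(·,j) / MI(·,·), and pairs are ranked and
   labelled intra-/inter-domain. Columns with >30 % gaps are removed first.

2. **Which residues relay signals across the complex?**
   Protein structure networks: residues are nodes, and an edge joins pairs
   with interaction strength I(i,j) = 100 · n_ij / √(N_i N_j) ≥ I_min, where
   n_ij counts heavy-atom contacts within 4.5 Å and N are per-residue-type
   normalization constants. I_min is chosen where the largest connected
   cluster collapses; edges present in ≥ 50 % of ensemble frames form the
   dynamically stable network. Shortest source→sink communication paths are
   computed per frame (Floyd–Warshall, hop counts), averaged, and intersected
   across sources to find residues every path passes through.

3. **How stable is the domain–domain interface?**
   Interface residues by a 5 Å heavy-atom criterion, hydrogen bonds by
   donor–acceptor geometry with per-pair ensemble **occupancy** (stable when
   strictly > 50 %), per-frame minimum-distance series, additive
   distance-threshold **pseudoenergies** (H-bond, electrostatic, van der
   Waals terms) with per-residue attribution and hotspot calling, plus
   standard conformational metrics (Kabsch-superposed backbone RMSD, radius
   of gyration, trailing-window Cα RMSF).

A first-class **synthetic-data module** generates alignments with planted
column couplings and toy two-chain complexes with planted contacts,
hydrogen bonds and communication paths, so the whole pipeline runs — and is
tested against known ground truth — without any external downloads.

## Worked example

```bash
python examples/01_coevolution.py
```

```
rank  i    j    MI      MIp     class
1     8    40   1.6601  +0.9914  inter
2     9    30   0.9232  +0.1573  inter
3     19   29   0.7841  +0.1284  inter
...
planted pair: (8, 40)
```

One inter-domain coupling (concatenated columns 8 and 40, strength 0.9) was
planted in a 100-sequence alignment; it is recovered at rank 1, with an MIp
six times the noise floor. The raw MI column shows why the correction
matters: finite-sample background inflates every pair, MIp subtracts it.

```bash
python examples/02_communication_paths.py
```

```
I_min at the largest-cluster transition: 2.5%
path A18 -> A27: A18-A21-A24-A27 (average 3.0 hops over 10 frames)
path A21 -> A27: A21-A24-A27 (average 2.0 hops over 10 frames)
intermediates shared by both paths: {'A24'}
```

The planted contact chain 18–21–24–27 is recovered exactly in every frame,
and intersecting two source→sink paths isolates the shared relay residue —
the toy analogue of finding the one residue all communication routes cross.

`examples/03_interface.py` shows the planted hydrogen bond at occupancy
0.70 (stable), the minimum-distance series jumping from 3.0 Å to 22.2 Å
when the interface separates, and pseudoenergies dropping to zero in the
broken frames. `examples/04_metrics_and_pipeline.py` prints per-frame
RMSD/Rg and runs the full pipeline from one config.

The same analyses are available from the shell:

```bash
interlock run --demo --seed 1 --out demo_out/      # full pipeline
interlock coevolve --msa-a a.fasta --msa-b b.fasta --top-n 24 --out pairs.tsv
interlock psn --ensemble traj.pdb --sources A18,A21 --sink A27 --imin auto --out paths.tsv
interlock interface --ensemble traj.pdb --chains A,B --out report/
interlock metrics --ensemble traj.pdb --rmsf-window 0.2 --out metrics.tsv
```

Inputs are aligned FASTA and (multi-model) PDB; all outputs are TSV with
the config hash recorded in a header comment, and reruns with the same
config and seed are byte-identical.

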