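# Methods

## Representation

An alignment is consumed raw. Sequences are read from flat aligned FASTA
(or A3M, after deleting lowercase insertion states) with the target
("master") sequence first; columns where the master has a gap are removed
so the width always equals the master length *L*. Each symbol maps to an
integer in 1..25: the 20 standard residues in alphabetical one-letter
order (A=1 … Y=20), then B=21, U=22, Z=23, X=24, gap "−"=25. Letters
outside this set (J, O, \*) collapse to X. The mapping is a convention —
any bijection would do — but it is fixed and documented so encodings are
reproducible. Index 0 is reserved for padding: depth is capped at the
first *Y* sequences in aligner output order, with all-zero rows appended
when fewer exist, and per-residue windows (width 31, odd by construction)
are zero-padded at the chain termini. Because real residues always encode
to integers > 0, padding can never be confused with sequence content.

The first network layer is a learned embedding: a 26 × *E* table mapping
every symbol (including the padding index, which owns a learnable row
like any other — documented so results are reproducible) to an *E*-vector
trained jointly with the predictor. Cosine similarity between embedding
rows (`embedding_similarity`) exposes what the network learned about
residue relatedness; similarity is ranked highest-first, i.e. lowest
cosine *distance*.

## Architectures

Both tasks share a column-local front end: 1 × *W* convolutions with ReLU
followed by 1 × *W* max pooling, acting only along the alignment-depth
axis. Perturbing alignment column *i* can therefore change the
per-position hidden tensor only at position *i* (verified by perturbation
tests). Pooling uses the floor rule when the depth is not divisible by
*W*; the filter count defaults to *E*, as does *W*.

**Per-residue (SS-RSA).** One conv/pool stage, then two stacked
bidirectional LSTMs over the 31 window columns (350 units per direction
at full scale; the last layer returns its concatenated final states),
then fully connected layers — two hidden layers (200 units at full scale,
a size fixed here by convention since only "three fully connected layers"
is prescribed) and a softmax class layer (3 SS, or 4/2 RSA classes).
Dropout (0.4–0.5 at full scale) follows each recurrent and dense layer.

**Pairwise (CMAP).** Up to six conv/pool stages, then the outer-product
expansion OP[i,j,f,s] = H[i,f,s]·H[j,f,s] reshaped to *L* × *L* × (*F*·*S*),
where *F* is the pooled alignment depth and *S* the filter count. The
pooled-depth axis survives the product, which is what lets pair channels
carry within-sequence co-occurrence (covariation) rather than only
column-marginal composition. A trunk of square 2D convolutions (kernels
3/5/10, 10–50 filters, 6–20 layers at full scale; ReLU then batch
normalization, zero-padded so one model serves any *L*) ends in a 2-channel
softmax map. The raw trunk output need not be symmetric; symmetry is
restored downstream by pair averaging (P[i,j]+P[j,i])/2 before any pair
is ranked — an order-invariant choice made here because no rule is
prescribed for collapsing the asymmetric map to a pair score.

Weights are Glorot-uniform initialized from a seeded generator; all
inference is deterministic given a checkpoint.

## Training protocol

Every optimization step consumes exactly one protein — all its windows,
or its full contact map — so batch size varies with protein length.
Optimizer: RMSprop (learning rate 1e-3 by default, the optimizer family's
conventional value; nothing else is prescribed), loss: sparse categorical
cross-entropy. A random 10% of the training *proteins* is reserved for
validation; splitting by protein rather than by window avoids leakage
between a protein's own overlapping windows. Per-residue models keep the
checkpoint with the highest validation accuracy (earliest epoch on ties);
contact models monitor validation loss instead, because plain accuracy is
nearly constant under the heavy contact/non-contact imbalance, and
support early stopping with a patience parameter (default 10 epochs).
Gradient clipping is off by default and exposed for long-protein
stability.

## Labels

Secondary structure and absolute accessible areas come from DSSP output
files (DSSP itself is not run). The eight DSSP states reduce to three by
the standard mapping {H,G,I}→H, {E,B}→E, {S,T,C,blank}→C. RSA is the DSSP
area divided by the residue's theoretical maximum accessible surface
area; the MaxASA table ships as overridable configuration with the
standard theoretical values, and RSA is clipped at 1.0 when DSSP's area
exceeds the maximum so the class intervals stay total. Class thresholds
are right-closed: four classes at [0,0.04], (0.04,0.25], (0.25,0.5],
(0.5,1] (Buried, PartiallyBuried, PartiallyAccessible, Accessible), two
classes at [0,0.25], (0.25,1]. Contacts are residue pairs whose Cβ atoms
(Cα for glycine; Cα fallback when a Cβ is missing from the model) lie
*strictly* below 8 Å. Residues without coordinates are masked, never
imputed, and masked pairs are excluded from ranking and denominators.
Indexing is 1-based; "long range" means separation |i−j| > 23, i.e. ≥ 24.

## Evaluation

Q3/Q4/Q2 are correct/total over unmasked residues. Contact precision
ranks eligible upper-triangle long-range pairs by predicted probability
(ties broken by ascending (i,j)) and takes the top ⌊L/5⌋ (minimum 1;
if fewer eligible pairs exist, the denominator is those actually
selected — the rounding rule matches common CASP tooling). The metric
depends only on the ranking, so it is invariant to monotone transforms of
the scores. Dataset numbers are unweighted means over targets.

## Homolog-safe splitting

Chains are assigned to structural superfamilies (ECOD/SCOPe-style
tables); chains mapping to more than one superfamily — or to none — are
removed. Folds are built by greedy bin packing: superfamilies
largest-first into the currently smallest fold, with a seeded shuffle
breaking size ties. The only hard constraint inherited from the protocol
is that no superfamily may span two folds; greedy balancing is this
package's choice, and guarantees max−min fold size never exceeds the
largest superfamily.

## Synthetic data

The generators produce desk-scale data carrying exactly the statistical
structure the networks must exploit, so the whole pipeline is testable
without sequence databases or the PDB.

* **SS/RSA generator** (`generate_ss_msa`): a hidden per-column class
  path from a sticky Markov chain (stay probability 0.9, uniform
  stationary distribution), with each of *N* sequences emitting, per
  column, a residue from a class-enriched set with probability 0.7
  (H:{A,E,L,M}, E:{V,I,Y,W}, C:{G,P,N,S}) and uniformly otherwise; gaps
  at rate 0.05. RSA labels follow an analogous independent 4-state chain
  with hydrophobicity-motivated sets; a `signal="rsa"` switch makes
  burial the emitted signal instead. The master row receives no gaps —
  otherwise master-gap-column removal would shift the labels off their
  positions — but is otherwise emitted by the same process as every
  other row.
* **Contact generator** (`generate_contact_msa`): planted long-range
  column pairs (5% of eligible pairs) co-emit complementary charge pairs
  (K↔E, R↔D) with probability 0.8 per sequence, against an independent
  uniform background. Pairs are coupled row-by-row in random order
  without overwriting cells already claimed by another pair in that row,
  so every planted pair retains covariation even when pairs share a
  column. The truth map is the planted set (symmetric; diagonal 1 by the
  zero-self-distance convention, never evaluated).
* **Toy structures** (`generate_toy_structure`): a straight 3.8 Å-spaced
  chain under a seeded random rigid motion, whose contact map is known
  analytically (|i−j| ≤ 2 at the 8 Å cutoff), for cross-checking the
  coordinate-based contact routine.

All generators are pure functions of (configuration, seed). They model
neither phylogenetic correlation between sequences nor realistic indels;
passing learnability tests therefore shows the architectures can extract
planted composition and covariation signal from raw alignments, not that
they reach any particular accuracy on real proteins.

## Desk-scale experiment sizes

The bundled experiments (`rawmsa.experiments`) use sizes chosen once as
realistic for a single CPU: the secondary-structure run trains on 160
synthetic proteins of L=60 (9,600 residues, comfortably above the 2,000
minimum the learnability check calls for) with a tiny model (E=8, Y=20,
16 LSTM units per direction, one 1×4 conv/pool stage with 16 filters,
one 64-unit dense layer, no dropout, learning rate 3e-3, 5 epochs) and
scores 20 held-out proteins; typical held-out Q3 is 0.91–0.95 against a
~0.36 majority baseline. The contact run trains on 40 proteins of L=60
with 24 sequences each (E=4, pool 1×2, 8 filters, a 3-layer 3×3 trunk,
up to 25 epochs, checkpoint by validation loss) and scores 6 held-out
targets; typical top-L/5 long-range precision is 0.65–0.85 against a
~0.05 random-ranking baseline. The fine (1×2) pooling matters for
contacts: coarser pooling averages away the within-row co-occurrence the
outer product must carry.

## Numerical choices and limitations

The autodiff engine computes in float64; softmax heads are validated to
sum to 1 within 1e-6, and ensemble inputs to within 1e-4. Batch
normalization keeps running statistics (momentum 0.9) for inference.
Ensembling requires all alignment sources for a target to agree exactly
on the master row and fails loudly otherwise rather than truncating.

Known limitations: training at the published scale (thousands of PDB
chains, alignment depths of 1000+) is out of reach of a pure-numpy
engine; no distance prediction (contacts only); no 8-class secondary
structure; mmCIF is unsupported beyond what Cβ/Cα extraction needs; the
paired-alignment ensemble consumes alignments as files and never runs an
aligner itself.
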