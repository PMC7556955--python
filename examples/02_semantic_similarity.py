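"""Disease semantic similarity from ancestor DAGs, and MISIM on top of it.

Two diseases are similar when their ontology DAGs share ancestors: the
layer-decay model weighs an ancestor by 0.5 per level towards the root, the
prevalence model by -log of the fraction of disease DAGs containing it; the
package averages the two. MISIM then scores two miRNAs by the average
best-match similarity between their associated disease groups.
"""

from mccmf import DiseaseDAGCollection, disease_semantic_similarity, misim

# tiny ontology: A and B share parent p; C is an isolated root
dags = DiseaseDAGCollection(
    diseases=["A", "B", "C"],
    ancestors={
        "A": frozenset({"A", "p"}),
        "B": frozenset({"B", "p"}),
        "C": frozenset({"C"}),
    },
    parent_edges={
        "A": frozenset({("A", "p")}),
        "B": frozenset({("B", "p")}),
        "C": frozenset(),
    },
)
ds = disease_semantic_similarity(dags)
print("disease semantic similarity (order A, B, C):")
print(ds.values.round(4))
# DS(A,B) averages the layer-decay value 1/3 with the prevalence-model
# value ~0.270: shared ancestry, but the shared parent p is fairly common.

mf = misim(ds, {"mir-a": ["A"], "mir-b": ["B"], "mir-c": ["C"]})
print("\nMISIM from single-disease groups (order mir-a, mir-b, mir-c):")
print(mf.values.round(4))
# mir-a and mir-b inherit exactly DS(A,B); mir-c shares no ancestry, so 0.
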