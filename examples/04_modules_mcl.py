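"""Partition a coexpression network into modules with Markov clustering.

MCL alternates expansion (random-walk spreading) and inflation (entry-wise
powering that starves weak flow); inflation 1.8 is the conventional setting
for biological networks. Modules are named Module-1, Module-2, ... by
descending size.
"""

from coexnet import correlation_matrix, mcl_cluster, threshold_network
from coexnet.synthetic import default_design, generate_dataset

m, truth = generate_dataset(default_design(seed=0))
net = threshold_network(correlation_matrix(m, "pcc"), 0.6)
print(f"network: {net.n_nodes} nodes, {net.n_edges} edges at r >= 0.6")

partition = mcl_cluster(net, inflation=1.8)
print(f"MCL found {partition.n_modules} modules "
      f"(converged={partition.converged} in {partition.iterations} iterations)")
for name, size in list(partition.sizes().items())[:6]:
    members = dict(partition.modules)[name]
    planted = {truth.module_of[g] for g in members}
    print(f"  {name}: {size} genes, planted labels {sorted(planted)}")
# The six largest MCL modules line up with the six planted modules; trailing
# singletons are background genes that picked up a stray edge.
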