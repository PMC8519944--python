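{
  "weights": {
    "in_degree": 0.06706364469274377,
    "out_degree": 0.0631266650333839,
    "in_degree_entropy": 0.06957949948565148,
    "out_degree_entropy": 0.06718663760954896,
    "transitivity": 0.061774644630591506,
    "pagerank": 0.07850164806828,
    "community_count": 0.0279421153460688,
    "motifs3": 0.041137948281215704,
    "motifs4": 0.047978771781205125,
    "markov_in_degree": 0.07591898047088631,
    "markov_out_degree": 0.06292768335945079,
    "markov_in_degree_entropy": 0.07497969514690325,
    "markov_out_degree_entropy": 0.0,
    "markov_transitivity": 0.05766519182091495,
    "markov_pagerank": 0.07585514248295455,
    "markov_community_count": 0.011675624212026245,
    "markov_motifs3": 0.06080412145388634,
    "markov_motifs4": 0.055881986124288414
  },
  "provenance": {
    "panel_size": 300,
    "explained_variance": 0.3778603874841641,
    "kind": "default",
    "seed": 0,
    "n_networks": 300,
    "n_nodes": 20
  }
}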