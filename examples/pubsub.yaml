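# Minimal publisher -> relay -> subscriber benchmark chain.
# Run with:  neuroloop run-graph examples/pubsub.yaml --duration 5
graph_name: pubsub_demo
bus:
  transport: tcp
  host: 127.0.0.1
  port: 6380
nodes:
  - nickname: pub
    executable: neuroloop.nodes:publisher
    parameters: {channels: 128, rate_hz: 1000, output_stream: raw}
    output_streams: [raw]
  - nickname: relay
    executable: neuroloop.nodes:forwarder
    parameters: {input_stream: raw, output_stream: relayed}
    input_streams: [raw]
    output_streams: [relayed]
  - nickname: sink
    executable: neuroloop.nodes:subscriber
    parameters: {input_stream: relayed, output_stream: receipts}
    input_streams: [relayed]
    output_streams: [receipts]
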