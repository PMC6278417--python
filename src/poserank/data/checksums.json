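{
 "active_site.txt": "60b070debb59fb7cf9080c08dd375bcddae537bd0c6c1ba4b1b77632dbd2b3e8",
 "best_pose_summary.csv": "87834b71f5ac06ecaed892e902cb04ec1bd7688106f8a089167cb8f67677197a",
 "expert1_pcm.csv": "76a0804a593d1ce2b19ec3812f4ffa8230d742b6ceaeb12ed29b256dde218663",
 "expert2_pcm.csv": "bce5493cb7a5652d672932cd020747e8744395a1cac07d25167858bf1560d0bc",
 "expert3_pcm.csv": "b3c9ea4781b6754382ab5792b7a3f68cb6ab952216c2cc034dcd876c244bb0d6",
 "expert4_pcm.csv": "4c5dd4f290125adf46111cb2901b29ac9fefc2b5d70a13ba8689dfb7de71839c",
 "group_pcm.csv": "c132183e3f0b38f2a09c5f5039610765fd6e4abd183f23aa8827816c7be4f5a2",
 "isatin_o_poses.csv": "bdf2b6bfa8002a90746e4736bb434ebbb062ccaee326639fe23d3602958b8850",
 "obidoxime_poses.csv": "981ec9c969018edc9f07b1aa0709297bdac733952b3838fae9c5b456c45059ab"
}
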