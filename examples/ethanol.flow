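#!/usr/bin/env atomflow
{
 "format_version": 1,
 "variables": {
  "smiles": "CCO"
 },
 "start": "n1",
 "nodes": {
  "n1": {
   "module_id": "atomflow.steps",
   "class_id": "ForceField",
   "version": "1.0.0",
   "parameters": {
    "text": "[types]\nX [*] 0 0\n"
   }
  },
  "n2": {
   "module_id": "atomflow.steps",
   "class_id": "Packing",
   "version": "1.0.0",
   "parameters": {
    "smiles": "${smiles}",
    "density": 0.3,
    "target_atoms": 90,
    "pack": true
   }
  },
  "n3": {
   "module_id": "atomflow.steps",
   "class_id": "Dynamics",
   "version": "1.0.0",
   "parameters": {
    "n_frames": 2000,
    "density": 0.803
   }
  }
 },
 "edges": [
  ["n1", "next", "n2"],
  ["n2", "next", "n3"]
 ]
}
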