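{
  "battery": "cognitive-control + episodic-memory screening battery (revised, 14 sub-scores)",
  "subtasks": [
    {
      "id": "WMCUT_S1",
      "label": "Working Memory Capacity & Updating Task, subtask 1 (short-term store)",
      "kind": "performance_score",
      "min_score": null,
      "max_score": null,
      "orientation": "higher_better",
      "aliases": ["WMCUT S 1", "WMCUT S1"]
    },
    {
      "id": "WMCUT_S2",
      "label": "Working Memory Capacity & Updating Task, subtask 2 (central executive)",
      "kind": "performance_score",
      "min_score": null,
      "max_score": null,
      "orientation": "higher_better",
      "aliases": ["WMCUT S 2", "WMCUT S2"]
    },
    {
      "id": "WMCUT_S3",
      "label": "Working Memory Capacity & Updating Task, subtask 3 (updating / episodic buffer)",
      "kind": "performance_score",
      "min_score": null,
      "max_score": null,
      "orientation": "higher_better",
      "aliases": ["WMCUT S 3", "WMCUT S3"]
    },
    {
      "id": "ACT",
      "label": "Attentional Control Task",
      "kind": "error_count",
      "min_score": null,
      "max_score": null,
      "orientation": "higher_worse",
      "aliases": []
    },
    {
      "id": "ICT_RST_12",
      "label": "Inhibitory Control & Task/Rule Switching Task, subtasks 1 & 2",
      "kind": "error_count",
      "min_score": null,
      "max_score": null,
      "orientation": "higher_worse",
      "aliases": ["ICT-RST 1 & 2", "ICT-RST 3"]
    },
    {
      "id": "ICT_RST_SE",
      "label": "Inhibitory Control & Task/Rule Switching Task, total switch errors",
      "kind": "error_count",
      "min_score": null,
      "max_score": null,
      "orientation": "higher_worse",
      "aliases": ["ICT-RST 1 & 2 SE", "ICT-RST SE", "ICT-RST SW", "ICT-RST 4a"]
    },
    {
      "id": "ICT_RST_FS",
      "label": "Inhibitory Control & Task/Rule Switching Task, failed sets",
      "kind": "error_count",
      "min_score": null,
      "max_score": null,
      "orientation": "higher_worse",
      "aliases": ["ICT-RST 1 & 2 FS", "ICT-RST FS", "ICT-RST 4b"]
    },
    {
      "id": "CFT",
      "label": "Cognitive Flexibility Task (part 1)",
      "kind": "error_count",
      "min_score": null,
      "max_score": null,
      "orientation": "higher_worse",
      "aliases": []
    },
    {
      "id": "CFT2_A",
      "label": "Cognitive Flexibility Task part 2, condition A (erroneous sets of 8)",
      "kind": "error_count",
      "min_score": 0,
      "max_score": 8,
      "orientation": "higher_worse",
      "aliases": ["CFT2 Con. a", "CFT Con. A"]
    },
    {
      "id": "CFT2_B",
      "label": "Cognitive Flexibility Task part 2, condition B (erroneous sets of 8)",
      "kind": "error_count",
      "min_score": 0,
      "max_score": 8,
      "orientation": "higher_worse",
      "aliases": ["CFT2 Con. b", "CFT Con. B"]
    },
    {
      "id": "CFT2_C",
      "label": "Cognitive Flexibility Task part 2, condition C (erroneous sets of 8)",
      "kind": "error_count",
      "min_score": 0,
      "max_score": 8,
      "orientation": "higher_worse",
      "aliases": ["CFT2 Con. c", "CFT Con. C"]
    },
    {
      "id": "VFT",
      "label": "Visual Fluency Task (distinct 4-pad orderings found in 60 s)",
      "kind": "correct_count",
      "min_score": 0,
      "max_score": 24,
      "orientation": "higher_better",
      "aliases": ["CFT2 Con. d"]
    },
    {
      "id": "EMTW_A",
      "label": "Episodic Memory Task (windows), condition A (recognition errors of 15)",
      "kind": "error_count",
      "min_score": 0,
      "max_score": 15,
      "orientation": "higher_worse",
      "aliases": ["EMT-W Con. a", "WINDOWS A"]
    },
    {
      "id": "EMTW_B",
      "label": "Episodic Memory Task (windows), condition B (recognition errors of 15)",
      "kind": "error_count",
      "min_score": 0,
      "max_score": 15,
      "orientation": "higher_worse",
      "aliases": ["EMT-W Con. b", "WINDOWS B"]
    }
  ]
}
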