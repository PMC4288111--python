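{
  "$defs": {
    "FieldModel": {
      "properties": {
        "col": {
          "title": "Col",
          "type": "integer"
        },
        "description": {
          "default": false,
          "title": "Description",
          "type": "boolean"
        },
        "directly_dependent": {
          "default": false,
          "title": "Directly Dependent",
          "type": "boolean"
        },
        "edition_disabled": {
          "default": false,
          "title": "Edition Disabled",
          "type": "boolean"
        },
        "is_id": {
          "default": false,
          "title": "Is Id",
          "type": "boolean"
        },
        "label": {
          "default": "",
          "title": "Label",
          "type": "string"
        },
        "mandatory": {
          "default": false,
          "title": "Mandatory",
          "type": "boolean"
        },
        "options": {
          "items": {
            "$ref": "#/$defs/OptionModel"
          },
          "title": "Options",
          "type": "array"
        },
        "property": {
          "title": "Property",
          "type": "string"
        },
        "row": {
          "title": "Row",
          "type": "integer"
        },
        "target": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Target"
        },
        "value_type": {
          "default": "string",
          "title": "Value Type",
          "type": "string"
        },
        "widget": {
          "title": "Widget",
          "type": "string"
        }
      },
      "required": [
        "property",
        "widget",
        "row",
        "col"
      ],
      "title": "FieldModel",
      "type": "object"
    },
    "MenuEntry": {
      "properties": {
        "label": {
          "title": "Label",
          "type": "string"
        },
        "property": {
          "title": "Property",
          "type": "string"
        },
        "target": {
          "title": "Target",
          "type": "string"
        }
      },
      "required": [
        "label",
        "property",
        "target"
      ],
      "title": "MenuEntry",
      "type": "object"
    },
    "OptionModel": {
      "properties": {
        "code": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Code"
        },
        "iri": {
          "title": "Iri",
          "type": "string"
        },
        "label": {
          "title": "Label",
          "type": "string"
        },
        "rank": {
          "title": "Rank",
          "type": "integer"
        }
      },
      "required": [
        "iri",
        "label",
        "rank"
      ],
      "title": "OptionModel",
      "type": "object"
    }
  },
  "description": "The compiled, renderable description of an application.",
  "properties": {
    "application": {
      "title": "Application",
      "type": "string"
    },
    "description_columns": {
      "additionalProperties": {
        "items": {
          "type": "string"
        },
        "type": "array"
      },
      "title": "Description Columns",
      "type": "object"
    },
    "forms": {
      "additionalProperties": {
        "items": {
          "$ref": "#/$defs/FieldModel"
        },
        "type": "array"
      },
      "title": "Forms",
      "type": "object"
    },
    "menu": {
      "items": {
        "$ref": "#/$defs/MenuEntry"
      },
      "title": "Menu",
      "type": "array"
    },
    "version": {
      "default": "1",
      "title": "Version",
      "type": "string"
    }
  },
  "required": [
    "application"
  ],
  "title": "FormModel",
  "type": "object"
}
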